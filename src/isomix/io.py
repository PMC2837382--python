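"""Readers and writers for the delimited-text table formats.

All files are comma-delimited with a required header row, decimal points
(no locale handling), and full float precision on output.

Formats
-------
consumers:       one column per isotope (header = isotope names).
sources / TEFs:  a leading name column, then alternating ``Mean<iso>`` /
                 ``SD<iso>`` column pairs.
concentrations:  a leading name column, then one column per isotope.

A missing TEF file means zero enrichment; a missing concentration file
means equal concentrations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ConcentrationTable,
    MixtureObservations,
    SourceTable,
    TEFTable,
)
from .posterior import PosteriorSummary
from .sampler import PosteriorDraws
from .simulate import CoverageReport, SimulatedDataset

__all__ = [
    "read_consumers",
    "read_sources",
    "read_tefs",
    "read_concentrations",
    "write_consumers",
    "write_sources",
    "write_tefs",
    "write_concentrations",
    "write_dataset",
    "read_dataset",
    "write_draws",
    "write_summary",
    "write_coverage",
]

_FLOAT_FMT = "%.17g"


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, header=0, skipinitialspace=True,
                     float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, path, cols) -> np.ndarray:
    out = np.empty((df.shape[0], len(cols)))
    for jc, c in enumerate(cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row + 1}, "
                f"column '{c}'"
            )
        out[:, jc] = col.to_numpy()
    return out


def read_consumers(path) -> MixtureObservations:
    """Read the N x J consumer delta-value matrix."""
    df = _read_table(path)
    values = _numeric(df, path, list(df.columns))
    return MixtureObservations(
        values=values, isotope_names=tuple(str(c) for c in df.columns)
    )


def _read_mean_sd(path, kind: str) -> tuple[tuple[str, ...], list[str], np.ndarray, np.ndarray]:
    df = _read_table(path)
    cols = list(df.columns)
    if len(cols) < 3 or (len(cols) - 1) % 2 != 0:
        raise ValueError(
            f"{path}: expected a name column plus Mean/SD column pairs, "
            f"got columns {cols}"
        )
    names = tuple(str(v) for v in df[cols[0]])
    mean_cols = cols[1::2]
    sd_cols = cols[2::2]
    isotopes = []
    for mc, sc in zip(mean_cols, sd_cols):
        iso_m = mc[4:] if mc.lower().startswith("mean") else mc
        iso_s = sc[2:] if sc.lower().startswith("sd") else sc
        if iso_m != iso_s:
            raise ValueError(
                f"{path}: column pair ('{mc}', '{sc}') names different isotopes"
            )
        isotopes.append(iso_m)
    means = _numeric(df, path, mean_cols)
    sds = _numeric(df, path, sd_cols)
    neg = np.argwhere(sds < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"{path}: negative SD at row {r + 1}, column '{sd_cols[c]}' "
            f"({kind} SDs must be non-negative)"
        )
    return names, isotopes, means, sds


def read_sources(path) -> SourceTable:
    """Read the source table: name, then Mean<iso>/SD<iso> pairs."""
    names, _isotopes, means, sds = _read_mean_sd(path, "source")
    return SourceTable(source_names=names, means=means, sds=sds)


def read_tefs(path=None, n_sources: int | None = None,
              n_isotopes: int | None = None) -> TEFTable:
    """Read the TEF table; ``path=None`` yields zero TEFs."""
    if path is None:
        if n_sources is None or n_isotopes is None:
            raise ValueError("need dimensions to build a zero TEF table")
        return TEFTable.zeros(n_sources, n_isotopes)
    _names, _isotopes, means, sds = _read_mean_sd(path, "TEF")
    return TEFTable(means=means, sds=sds)


def read_concentrations(path=None, n_sources: int | None = None,
                        n_isotopes: int | None = None) -> ConcentrationTable:
    """Read the concentration table; ``path=None`` yields equal concentrations."""
    if path is None:
        if n_sources is None or n_isotopes is None:
            raise ValueError("need dimensions to build a unit concentration table")
        return ConcentrationTable.ones(n_sources, n_isotopes)
    df = _read_table(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected a name column plus isotope columns")
    values = _numeric(df, path, cols[1:])
    return ConcentrationTable(values=values)


def write_consumers(data: MixtureObservations, path) -> None:
    pd.DataFrame(data.values, columns=list(data.isotope_names)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def _write_mean_sd(names, isotopes, means, sds, path, name_col: str) -> None:
    out = {name_col: list(names)}
    for j, iso in enumerate(isotopes):
        out[f"Mean{iso}"] = means[:, j]
        out[f"SD{iso}"] = sds[:, j]
    pd.DataFrame(out).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_sources(sources: SourceTable, isotope_names, path) -> None:
    _write_mean_sd(sources.source_names, isotope_names, sources.means,
                   sources.sds, path, "Source")


def write_tefs(tefs: TEFTable, source_names, isotope_names, path) -> None:
    _write_mean_sd(source_names, isotope_names, tefs.means, tefs.sds,
                   path, "Source")


def write_concentrations(conc: ConcentrationTable, source_names,
                         isotope_names, path) -> None:
    out = {"Source": list(source_names)}
    for j, iso in enumerate(isotope_names):
        out[iso] = conc.values[:, j]
    pd.DataFrame(out).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_dataset(ds: SimulatedDataset, prefix) -> dict[str, Path]:
    """Write a simulated dataset as a set of CSVs plus a truth JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    iso = ds.consumers.isotope_names
    paths = {
        "consumers": Path(f"{prefix}_consumers.csv"),
        "sources": Path(f"{prefix}_sources.csv"),
        "tefs": Path(f"{prefix}_tefs.csv"),
        "concentrations": Path(f"{prefix}_concentrations.csv"),
        "truth": Path(f"{prefix}_truth.json"),
    }
    write_consumers(ds.consumers, paths["consumers"])
    write_sources(ds.sources, iso, paths["sources"])
    write_tefs(ds.tefs, ds.sources.source_names, iso, paths["tefs"])
    write_concentrations(ds.concentrations, ds.sources.source_names, iso,
                         paths["concentrations"])
    truth = {
        "scenario": ds.scenario,
        "seed": ds.seed,
        "true_p": [float(v) for v in ds.true_p.p],
        "true_sigma": [float(v) for v in ds.true_sigma.sigma],
        "source_names": list(ds.sources.source_names),
        "isotope_names": list(iso),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def read_dataset(prefix) -> tuple[MixtureObservations, SourceTable, TEFTable, ConcentrationTable]:
    """Read back the four tables written by :func:`write_dataset`."""
    prefix = Path(prefix)
    consumers = read_consumers(f"{prefix}_consumers.csv")
    sources = read_sources(f"{prefix}_sources.csv")
    tefs = read_tefs(f"{prefix}_tefs.csv")
    conc = read_concentrations(f"{prefix}_concentrations.csv")
    return consumers, sources, tefs, conc


def write_draws(draws: PosteriorDraws, path) -> None:
    """Draw matrix as CSV: source columns first, then sigma columns."""
    cols = [f"p[{s}]" for s in draws.source_names] + [
        f"sigma[{i}]" for i in draws.isotope_names
    ]
    pd.DataFrame(
        np.hstack([draws.p_draws, draws.sigma_draws]), columns=cols
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_summary(summary: PosteriorSummary, path) -> None:
    """Summary as JSON keyed by parameter, including the interval level."""
    payload = {
        "interval_level": summary.level,
        "parameters": {
            name: {c: float(v) for c, v in row.items()}
            for name, row in summary.table.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_coverage(report: CoverageReport, path) -> None:
    """Coverage table as CSV: scenario, K, J, n, coverage, se."""
    out = report.table[["scenario", "K", "J", "n_datasets", "coverage", "se"]]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
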