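"""Tidy-CSV writers and readers for the four data tables.

All tables are one-row-per-observation CSV: counts (year, replicate, class,
sex, count), harvest tallies, mark-recapture detections (one row per
individual-year) and litter follow-ups (one row per litter-year).  Readers
for the CMR and litter tables -- which carry row-level validation -- live in
:mod:`bearipm.kodiak` and are re-exported here so every writer has a paired
reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import AgeClass, Sex
from .kodiak import read_cmr_table, read_litter_table
from .simulator import SimulatedDataset

__all__ = [
    "write_counts",
    "write_harvest",
    "write_cmr",
    "write_cmr_histories",
    "write_litters",
    "write_litter_records",
    "write_truth",
    "write_dataset",
    "read_counts",
    "read_harvest",
    "read_cmr_table",
    "read_litter_table",
    "write_posterior_summary",
]

_AGE_CODES = "CYDSA"
_SEX_CODES = "mf"


def write_counts(ds: SimulatedDataset, path) -> None:
    rows = [
        dict(
            year=c.year,
            replicate=c.replicate,
            age_class=c.age_class.code,
            sex=c.sex.code,
            count=c.count,
        )
        for c in ds.counts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts(path) -> np.ndarray:
    """Counts CSV back to the (T, K, 5, 2) array the models consume."""
    df = pd.read_csv(path)
    T = int(df.year.max()) + 1
    Krep = int(df.replicate.max()) + 1
    arr = np.zeros((T, Krep, 5, 2), dtype=np.int64)
    for row in df.itertuples():
        arr[
            row.year, row.replicate,
            _AGE_CODES.index(row.age_class), _SEX_CODES.index(row.sex),
        ] = row.count
    return arr


def write_harvest(ds: SimulatedDataset, path) -> None:
    rows = []
    for h in ds.harvests:
        for a in AgeClass:
            for s in Sex:
                rows.append(
                    dict(
                        year=h.year, age_class=a.code, sex=s.code,
                        harvest=int(h.h[a, s]),
                    )
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_harvest(path) -> np.ndarray:
    df = pd.read_csv(path)
    T = int(df.year.max()) + 1
    arr = np.zeros((T, 5, 2), dtype=np.int64)
    for row in df.itertuples():
        arr[row.year, _AGE_CODES.index(row.age_class), _SEX_CODES.index(row.sex)] = (
            row.harvest
        )
    return arr


def write_cmr_histories(histories, path) -> None:
    """One row per individual-year: detections, recoveries, repro status."""
    rows = []
    for h in histories:
        ages = h.covariates.get("age")
        dep = h.covariates.get("dep_young")
        for j in range(h.n_occasions):
            age = int(ages[j]) if ages is not None else h.age_at_entry + j
            repro = ""
            if h.repro is not None and age >= 5:
                repro = int(h.repro[j])
            rows.append(
                dict(
                    id=h.individual_id,
                    year=h.entry_year + j,
                    sex=h.sex.code,
                    age=age,
                    detected=int(h.y[j]),
                    recovered_dead=int(h.r[j]),
                    repro_status=repro,
                    dependent_young_age=(
                        1 if dep is not None and dep[j] > 0 else ""
                    ),
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cmr(ds: SimulatedDataset, path) -> None:
    write_cmr_histories(ds.cmr, path)


def write_litter_records(litters, path) -> None:
    """One row per litter-year with size and weaning flag."""
    rows = []
    for rec in litters:
        for age in range(rec.sizes.size):
            rows.append(
                dict(
                    litter_id=rec.litter_id,
                    mother_id=rec.mother_id,
                    year=rec.birth_year + age,
                    litter_age=age,
                    size=int(rec.sizes[age]),
                    weaned=int(rec.weaned_at == age) if rec.weaned_at else 0,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_litters(ds: SimulatedDataset, path) -> None:
    write_litter_records(ds.litters, path)


def write_truth(ds: SimulatedDataset, path) -> None:
    rows = []
    for st in ds.states:
        for a in AgeClass:
            for s in Sex:
                rows.append(
                    dict(
                        year=st.year, age_class=a.code, sex=s.code,
                        n_before_harvest=int(st.n_before_harvest[a, s]),
                        n=int(st.n[a, s]),
                    )
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write all four observation tables plus the simulation truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, writer in (
        ("counts", write_counts),
        ("harvest", write_harvest),
        ("cmr", write_cmr),
        ("litters", write_litters),
        ("truth", write_truth),
    ):
        path = outdir / f"{name}.csv"
        writer(ds, path)
        paths[name] = str(path)
    return paths


def write_posterior_summary(samples, path, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, credible bounds and R-hat per parameter, as CSV."""
    from .inference import gelman_rubin, summarize

    rows = []
    for name in samples.names:
        mean, lo, hi = summarize(samples, name, level)
        x = samples.get(name)
        rhat = (
            gelman_rubin(samples, name)
            if not np.allclose(x.var(axis=1), 0)
            else float("nan")
        )
        rows.append(dict(parameter=name, mean=mean, lower=lo, upper=hi, rhat=rhat))
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
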