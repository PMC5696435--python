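"""Packaged synthetic fixtures: a small case-study-shaped dataset.

The tables under ``bearipm/data/synthetic_kodiak`` are a deterministic,
synthetic stand-in for deposited case-study data (ten marked bears with
litter follow-ups and a salmon covariate), used by the readers' round-trip
tests and the documentation examples.  ``regenerate`` rebuilds them
byte-identically from the generator.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .kodiak import generate_synthetic_kodiak, read_cmr_table, read_litter_table

__all__ = ["fixture_dir", "regenerate", "load_fixture"]

_FIXTURE_SEED = 11
_N_INDIVIDUALS = 10
_N_YEARS = 10


def fixture_dir() -> Path:
    return Path(resources.files("bearipm")) / "data" / "synthetic_kodiak"


def regenerate(outdir=None) -> dict:
    """Rebuild the fixture tables; returns the manifest dict."""
    from .io import write_cmr_histories, write_litter_records

    outdir = Path(outdir) if outdir is not None else fixture_dir()
    outdir.mkdir(parents=True, exist_ok=True)
    histories, litters, cov = generate_synthetic_kodiak(
        n_individuals=_N_INDIVIDUALS, n_years=_N_YEARS, seed=_FIXTURE_SEED
    )
    write_cmr_histories(histories, outdir / "cmr.csv")
    write_litter_records(litters, outdir / "litters.csv")
    pd.DataFrame(
        {"year": range(_N_YEARS), "salmon_biomass": cov["salmon"]}
    ).to_csv(outdir / "salmon.csv", index=False)
    manifest = {
        "synthetic": True,
        "seed": _FIXTURE_SEED,
        "n_individuals": len(histories),
        "n_cmr_rows": int(sum(h.n_occasions for h in histories)),
        "n_litters": len(litters),
        "n_litter_years": int(sum(r.sizes.size for r in litters)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_fixture(directory=None):
    """Read the packaged fixture back through the standard readers."""
    d = Path(directory) if directory is not None else fixture_dir()
    histories = read_cmr_table(d / "cmr.csv")
    litters = read_litter_table(d / "litters.csv")
    salmon = pd.read_csv(d / "salmon.csv")
    covariates = {
        "salmon": salmon.salmon_biomass.to_numpy(),
        "year0": int(salmon.year.min()),
    }
    manifest = json.loads((d / "manifest.json").read_text())
    return histories, litters, covariates, manifest
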