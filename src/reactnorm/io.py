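"""CSV dialects, fit serialisation and reproducibility metadata.

Phenotypes travel as long-format CSV (one row per tree x year record):
``tree_id,site,year,covariate,<trait1>[,<trait2>]``.  Pedigrees are
``id,sire,dam,taxon`` with the empty string for an unknown parent.  Daily
series are ``date[,tree_id],value``.  A fitted model is serialised to a
directory: JSON metadata (model spec, gradient scale, chain settings,
package version, input checksums) plus one CSV per chain group.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import GradientScale
from .model import FitResult, MCMCConfig, ModelSpec
from .pedigree import Pedigree

__all__ = [
    "read_phenotypes",
    "read_pedigree",
    "read_daily",
    "save_fit",
    "load_fit",
    "file_checksum",
    "write_run_metadata",
]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require_columns(df: pd.DataFrame, cols, what: str, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} lacks column(s): {', '.join(missing)}")


def read_phenotypes(path, traits=None) -> pd.DataFrame:
    """Long phenotype table; rows with an unparsable covariate are reported."""
    df = pd.read_csv(path)
    _require_columns(df, ("tree_id", "site", "covariate"), "phenotype", path)
    bad = df.index[pd.to_numeric(df["covariate"], errors="coerce").isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"non-numeric covariate in {path} at line(s) {lines}")
    df["covariate"] = df["covariate"].astype(float)
    if traits:
        _require_columns(df, traits, "phenotype", path)
    return df


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ("id", "sire", "dam"), "pedigree", path)
    return Pedigree.from_dataframe(df)


def read_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("date", "value"), "daily series", path)
    df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# fit serialisation


def save_fit(fit: FitResult, outdir) -> Path:
    """Write a FitResult to a directory (JSON metadata + chain CSVs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    k = fit.spec.k
    meta = {
        "package_version": __version__,
        "spec": fit.spec.to_dict(),
        "scale": fit.scale.to_dict(),
        "config": fit.config.to_dict(),
        "sites": fit.sites,
        "stored_ids": fit.stored_ids,
        "ped_ids": fit.ped_ids,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))

    cov = {}
    for name in ("Sigma_A", "Sigma_HE", "Sigma_HJ", "Sigma_P"):
        if name in fit.draws:
            arr = fit.draws[name]
            for i in range(k):
                for j in range(i, k):
                    cov[f"{name}[{i},{j}]"] = arr[:, i, j]
    for t in range(fit.spec.n_traits):
        cov[f"sigma2_R[{t}]"] = fit.draws["sigma2"][:, t]
    pd.DataFrame(cov).to_csv(out / "chains_cov.csv", index=False)

    beta = fit.draws["beta"]
    pd.DataFrame(
        beta, columns=[f"beta[{j}]" for j in range(beta.shape[1])]
    ).to_csv(out / "chains_beta.csv", index=False)

    eff = {}
    if "u" in fit.draws:
        for p, id_ in enumerate(fit.stored_ids):
            for j in range(k):
                eff[f"{id_}[{j}]"] = fit.draws["u"][:, p, j]
    else:
        for label, key, ids in (
            ("gE", "gE", fit.draws["_e_parents"]),
            ("gJ", "gJ", fit.draws["_j_parents"]),
        ):
            for p, id_ in enumerate(ids):
                for j in range(k):
                    eff[f"{label}:{id_}[{j}]"] = fit.draws[key][:, p, j]
    pd.DataFrame(eff).to_csv(out / "chains_effects.csv", index=False)

    if fit.u_mean is not None:
        pd.DataFrame(
            fit.u_mean, index=fit.ped_ids, columns=[f"c{j}" for j in range(k)]
        ).to_csv(out / "u_mean.csv", index_label="id")
    return out


def load_fit(indir) -> FitResult:
    """Reload a serialised fit (without the training-data design)."""
    ind = Path(indir)
    meta = json.loads((ind / "meta.json").read_text())
    sd = meta["spec"]
    spec = ModelSpec(
        order=sd["order"],
        traits=tuple(sd["traits"]),
        include_permanent=sd["include_permanent"],
        taxon_mode=sd["taxon_mode"],
        hybrid_taxon=sd.get("hybrid_taxon", "HL"),
        species=tuple(sd.get("species", ("EL", "JL"))),
    )
    cfg = MCMCConfig(**meta["config"])
    k = spec.k

    cov = pd.read_csv(ind / "chains_cov.csv")
    n_draws = len(cov)
    draws: dict = {}
    for name in ("Sigma_A", "Sigma_HE", "Sigma_HJ", "Sigma_P"):
        if f"{name}[0,0]" in cov.columns:
            arr = np.empty((n_draws, k, k))
            for i in range(k):
                for j in range(i, k):
                    arr[:, i, j] = arr[:, j, i] = cov[f"{name}[{i},{j}]"]
            draws[name] = arr
    draws["sigma2"] = np.column_stack(
        [cov[f"sigma2_R[{t}]"] for t in range(spec.n_traits)]
    )
    beta = pd.read_csv(ind / "chains_beta.csv")
    draws["beta"] = beta.to_numpy()

    eff = pd.read_csv(ind / "chains_effects.csv")
    stored_ids = meta["stored_ids"]
    if spec.taxon_mode == "pure":
        u = np.empty((n_draws, len(stored_ids), k))
        for p, id_ in enumerate(stored_ids):
            for j in range(k):
                u[:, p, j] = eff[f"{id_}[{j}]"]
        draws["u"] = u
    else:
        e_ids = [i for i in stored_ids if f"gE:{i}[0]" in eff.columns]
        j_ids = [i for i in stored_ids if f"gJ:{i}[0]" in eff.columns]
        for label, ids in (("gE", e_ids), ("gJ", j_ids)):
            arr = np.empty((n_draws, len(ids), k))
            for p, id_ in enumerate(ids):
                for j in range(k):
                    arr[:, p, j] = eff[f"{label}:{id_}[{j}]"]
            draws[label] = arr
        draws["_e_parents"] = e_ids
        draws["_j_parents"] = j_ids

    u_mean = None
    if (ind / "u_mean.csv").exists():
        um = pd.read_csv(ind / "u_mean.csv", index_col="id")
        u_mean = um.to_numpy()

    return FitResult(
        spec=spec,
        scale=GradientScale.from_dict(meta["scale"]),
        config=cfg,
        sites=meta["sites"],
        stored_ids=stored_ids,
        draws=draws,
        u_mean=u_mean,
        p_mean=None,
        ped_ids=meta["ped_ids"],
        model=None,
    )


def write_run_metadata(outdir, config: dict, inputs: dict | None = None) -> Path:
    """Reproducibility contract: resolved config, version and input checksums."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "package_version": __version__,
        "config": config,
        "input_checksums": {
            str(name): file_checksum(p) for name, p in (inputs or {}).items()
        },
    }
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=1))
    return path
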