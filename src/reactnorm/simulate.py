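"""Synthetic diallel populations with environment-dependent allelic effects.

The generator emulates a forward, purely additive genetic model: a genome
of X diallelic loci where each allele's contribution to the phenotype is a
parabola of the environment,

    alpha(x) = alpha0 + alpha1 (x + delta) + alpha2 (x + delta)^2.

Founder alleles are drawn uniformly from configured ranges chosen so that
the resulting reaction norms are strongly interactive (parental rankings
change along the gradient).  Ten monoecious founders are mated in a full
diallel excluding selfs: each ordered cross A x B produces n/2 sibs, so a
full-sib family (A x B plus B x A) has size n.  The gradient is divided in
n random positions; every environment hosts exactly one sib per family, and
each progeny contributes a single phenotypic record at its environment
(optionally several, for repeated-records experiments).

Because every allelic effect is a quadratic in x, a genotype's value is
itself a quadratic; genomes are therefore summarised by three aggregated
polynomial coefficients, which makes true breeding values evaluable at any
gradient point.  The residual standard deviation is calibrated against the
realized additive variance at the assigned environments so that the dataset
hits a target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "EffectRanges",
    "Scenario",
    "SCENARIOS",
    "SimulatedDiallelDataset",
    "sample_founders",
    "mate_diallel",
    "assign_environments",
    "calibrate_residual",
    "simulate_dataset",
]


@dataclass(frozen=True)
class EffectRanges:
    """Uniform sampling ranges for allelic parabola parameters."""

    alpha0: tuple = (-1.0, 1.0)
    alpha1: tuple = (-0.5, 0.5)
    alpha2: tuple = (-0.25, 0.25)
    delta: tuple = (-1.0, 1.0)

    def __post_init__(self):
        for name in ("alpha0", "alpha1", "alpha2", "delta"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and hi >= lo):
                raise ValueError(f"invalid range for {name}: {(lo, hi)}")


@dataclass(frozen=True)
class Scenario:
    """Simulation scenario: target heritability and family size."""

    target_h2: float
    family_size: int
    replicates: int = 100
    orders: tuple = (0, 1, 2)
    seed: int = 0

    def __post_init__(self):
        if self.family_size % 2:
            raise ValueError("family size must be even (n/2 sibs per ordered cross)")
        if not 0 < self.target_h2 <= 1:
            raise ValueError("target heritability must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


#: the four study scenarios: low/high heritability x small/large families
SCENARIOS = {
    1: Scenario(target_h2=0.1, family_size=20),
    2: Scenario(target_h2=0.1, family_size=120),
    3: Scenario(target_h2=0.6, family_size=20),
    4: Scenario(target_h2=0.6, family_size=120),
}


def _quad_coeffs(params: np.ndarray) -> np.ndarray:
    """(alpha0, alpha1, alpha2, delta) -> polynomial coefficients (c0, c1, c2).

    alpha0 + alpha1 (x+d) + alpha2 (x+d)^2  ==  c0 + c1 x + c2 x^2.
    """
    a0, a1, a2, d = np.moveaxis(params, -1, 0)
    return np.stack([a0 + a1 * d + a2 * d * d, a1 + 2 * a2 * d, a2], axis=-1)


def _eval_quad(coeffs: np.ndarray, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return coeffs[..., 0] + coeffs[..., 1] * x + coeffs[..., 2] * x**2


def sample_founders(
    n_founders: int = 10,
    n_loci: int = 100,
    ranges: EffectRanges | None = None,
    seed=None,
) -> np.ndarray:
    """Sample founder genomes: array (n_founders, n_loci, 2, 4).

    The last axis holds (alpha0, alpha1, alpha2, delta) for each of the two
    alleles at a locus, drawn uniformly from the configured ranges.
    """
    ranges = ranges or EffectRanges()
    rng = np.random.default_rng(seed)
    out = np.empty((n_founders, n_loci, 2, 4))
    for j, name in enumerate(("alpha0", "alpha1", "alpha2", "delta")):
        lo, hi = getattr(ranges, name)
        out[..., j] = rng.uniform(lo, hi, size=(n_founders, n_loci, 2))
    return out


def mate_diallel(n_founders: int, family_size: int, seed=None):
    """Full diallel excluding selfs: progeny sire/dam/family indices.

    All ordered crosses A x B with A != B each contribute family_size/2
    sibs; ``family`` identifies the unordered parent pair, pooling the
    reciprocal crosses into one full-sib family.  For 10 founders this
    yields 90 ordered crosses, 45 families and 45*family_size progeny.
    """
    if family_size % 2:
        raise ValueError("family size must be even")
    if n_founders < 2:
        raise ValueError("need at least two founders")
    sire, dam, family = [], [], []
    fam_of = {}
    for a in range(n_founders):
        for b in range(n_founders):
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            fam = fam_of.setdefault(key, len(fam_of))
            for _ in range(family_size // 2):
                sire.append(a)
                dam.append(b)
                family.append(fam)
    return np.array(sire), np.array(dam), np.array(family)


def assign_environments(family_size: int, gradient=(-1.0, 1.0), seed=None):
    """Divide the gradient in ``family_size`` random positions."""
    lo, hi = gradient
    if not hi > lo:
        raise ValueError("degenerate gradient range")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=family_size)


def calibrate_residual(genetic_values, target_h2: float) -> float:
    """Residual sd giving the target heritability for these genetic values.

    ``genetic_values`` are additive deviations at the progeny's assigned
    environments; sd = sqrt(Var * (1 - h2) / h2).
    """
    g = np.asarray(genetic_values, dtype=float)
    vg = float(np.var(g))
    if vg == 0:
        raise ValueError("zero genetic variance: cannot calibrate residual")
    if not 0 < target_h2 <= 1:
        raise ValueError("target heritability must lie in (0, 1]")
    return float(np.sqrt(vg * (1.0 - target_h2) / target_h2))


@dataclass
class SimulatedDiallelDataset:
    """One simulated diallel with truth for every evaluation."""

    founders: np.ndarray          # (F, L, 2, 4) allelic parameters
    founder_coeffs: np.ndarray    # (F, 3) genotypic quadratic per founder
    progeny_coeffs: np.ndarray    # (P, 3)
    sire: np.ndarray              # (P,) founder index
    dam: np.ndarray
    family: np.ndarray
    gam_s: np.ndarray             # (P, L) allele chosen from the sire
    gam_d: np.ndarray
    env: np.ndarray               # (P,) assigned environmental value
    env_positions: np.ndarray     # (n,) the gradient positions
    phenotype: np.ndarray         # (P,)
    perm_effect: np.ndarray       # (P,) permanent-environment deviation
    residual_sd: float
    target_h2: float
    extra_records: pd.DataFrame | None = None  # repeated-records design

    # -- truth -----------------------------------------------------------
    @property
    def n_founders(self) -> int:
        return self.founders.shape[0]

    @property
    def n_progeny(self) -> int:
        return self.sire.size

    def founder_ids(self) -> list:
        return [f"F{i}" for i in range(self.n_founders)]

    def true_performance(self, x) -> np.ndarray:
        """True additive performances of the founders at x.

        Centered by the founder-population mean at x (under pure
        additivity a founder's breeding value is its genotypic deviation).
        Returns shape (F,) for scalar x, (F, len(x)) otherwise.
        """
        dev = self.founder_coeffs - self.founder_coeffs.mean(axis=0)
        x = np.asarray(x, dtype=float)
        return dev[:, 0, None] + dev[:, 1, None] * x + dev[:, 2, None] * x**2 if x.ndim else (
            dev[:, 0] + dev[:, 1] * x + dev[:, 2] * x**2
        )

    def progeny_deviation(self, at=None) -> np.ndarray:
        """Progeny additive deviations from the population mean curve.

        Evaluated at each progeny's own environment (default) or at ``at``.
        """
        dev = self.progeny_coeffs - self.progeny_coeffs.mean(axis=0)
        x = self.env if at is None else np.full(self.n_progeny, at, dtype=float)
        return dev[:, 0] + dev[:, 1] * x + dev[:, 2] * x**2

    def true_additive_variance(self, x) -> np.ndarray:
        """Variance across founders of their true additive performances at x.

        The founders are the base population of the fitted animal model, so
        the realized spread of their performance functions is the additive
        variance the model can be asked to recover from a single diallel.
        """
        dev = self.founder_coeffs - self.founder_coeffs.mean(axis=0)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        vals = dev[:, 0, None] + dev[:, 1, None] * x[None] + dev[:, 2, None] * x[None] ** 2
        v = vals.var(axis=0)
        return v if v.size > 1 else float(v[0])

    def realized_heritability(self) -> float:
        """Var(true additive deviations) / Var(phenotype net of the mean curve).

        The mean reaction norm (fixed part) is removed from the phenotype
        before taking the variance, as fixed effects do not enter the
        phenotypic variance of a heritability.
        """
        g = self.progeny_deviation()
        mean_curve = _eval_quad(self.progeny_coeffs.mean(axis=0)[None], self.env)[0]
        y_centred = self.phenotype - mean_curve
        return float(np.var(g) / np.var(y_centred))

    # -- export ----------------------------------------------------------
    def progeny_ids(self) -> list:
        return [f"P{i}" for i in range(self.n_progeny)]

    def pedigree(self) -> Pedigree:
        recs = [(f"F{i}", None, None, "SIM") for i in range(self.n_founders)]
        recs += [
            (f"P{i}", f"F{self.sire[i]}", f"F{self.dam[i]}", "SIM")
            for i in range(self.n_progeny)
        ]
        return Pedigree.from_records(recs)

    def phenotypes(self) -> pd.DataFrame:
        """Long phenotype table in the dialect the model consumes."""
        base = pd.DataFrame(
            {
                "tree_id": self.progeny_ids(),
                "site": "S1",
                "year": 0,
                "covariate": self.env,
                "y": self.phenotype,
            }
        )
        if self.extra_records is not None:
            base = pd.concat([base, self.extra_records], ignore_index=True)
        return base

    def truth_table(self, x_grid) -> pd.DataFrame:
        x_grid = np.asarray(x_grid, dtype=float)
        perf = self.true_performance(x_grid)
        rows = []
        for i, fid in enumerate(self.founder_ids()):
            for g, x in enumerate(x_grid):
                rows.append({"founder": fid, "x": x, "true_performance": perf[i, g]})
        return pd.DataFrame(rows)


def simulate_dataset(
    target_h2: float = 0.6,
    family_size: int = 120,
    n_founders: int = 10,
    n_loci: int = 100,
    ranges: EffectRanges | None = None,
    gradient=(-1.0, 1.0),
    records_per_individual: int = 1,
    perm_sd: float = 0.0,
    seed=None,
) -> SimulatedDiallelDataset:
    """Run the full generator: founders -> diallel -> environments -> records.

    One master seed drives every random draw; re-running with the same seed
    reproduces the dataset bit for bit.  With ``records_per_individual > 1``
    each progeny receives additional records at fresh uniform environments,
    plus an individual-level permanent-environment deviation of sd
    ``perm_sd`` shared by all its records (a repeated-records design for
    subsampling experiments).
    """
    rng = np.random.default_rng(seed)
    founders = sample_founders(n_founders, n_loci, ranges, seed=rng)
    founder_coeffs = _quad_coeffs(founders).sum(axis=(1, 2))

    sire, dam, family = mate_diallel(n_founders, family_size, seed=rng)
    P = sire.size
    gam_s = rng.integers(0, 2, size=(P, n_loci))
    gam_d = rng.integers(0, 2, size=(P, n_loci))
    allele_coeffs = _quad_coeffs(founders)  # (F, L, 2, 3)
    loci = np.arange(n_loci)
    progeny_coeffs = (
        allele_coeffs[sire[:, None], loci[None, :], gam_s]
        + allele_coeffs[dam[:, None], loci[None, :], gam_d]
    ).sum(axis=1)

    env_positions = assign_environments(family_size, gradient, seed=rng)
    env = np.empty(P)
    n_fam = family.max() + 1
    for f in range(n_fam):
        members = np.flatnonzero(family == f)
        env[members] = env_positions[rng.permutation(family_size)]

    dev = progeny_coeffs - progeny_coeffs.mean(axis=0)
    g_at_env = dev[:, 0] + dev[:, 1] * env + dev[:, 2] * env**2
    residual_sd = calibrate_residual(g_at_env, target_h2)

    perm = rng.normal(0.0, perm_sd, size=P) if perm_sd > 0 else np.zeros(P)
    mean_coeffs = progeny_coeffs.mean(axis=0)
    genetic_total = _eval_quad(progeny_coeffs, env)
    phenotype = genetic_total + perm + rng.normal(0.0, residual_sd, size=P)

    extra = None
    if records_per_individual > 1:
        lo, hi = gradient
        rows = []
        for rrec in range(records_per_individual - 1):
            xr = rng.uniform(lo, hi, size=P)
            yr = _eval_quad(progeny_coeffs, xr) + perm + rng.normal(
                0.0, residual_sd, size=P
            )
            rows.append(
                pd.DataFrame(
                    {
                        "tree_id": [f"P{i}" for i in range(P)],
                        "site": "S1",
                        "year": rrec + 1,
                        "covariate": xr,
                        "y": yr,
                    }
                )
            )
        extra = pd.concat(rows, ignore_index=True)

    return SimulatedDiallelDataset(
        founders=founders,
        founder_coeffs=founder_coeffs,
        progeny_coeffs=progeny_coeffs,
        sire=sire,
        dam=dam,
        family=family,
        gam_s=gam_s,
        gam_d=gam_d,
        env=env,
        env_positions=env_positions,
        phenotype=phenotype,
        perm_effect=perm,
        residual_sd=residual_sd,
        target_h2=target_h2,
        extra_records=extra,
    )
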