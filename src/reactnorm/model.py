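"""Random-regression mixed models on a pedigree, fitted by Gibbs sampling.

The phenotype of record *l* of individual *k* (genotype *j*, site *i*) at
environmental value *x* is modelled as

    y_ijkl(x) = sum_m s_im L_m(x') + sum_m a_jm L_m(x') + sum_m p_km L_m(x') + r

with L_m the m-th Legendre polynomial of the standardized covariate x'.
Site curves *s* are fixed; additive coefficient vectors *a* are random with
covariance ``Sigma_A ⊗ A`` (A the numerator relationship matrix); the
permanent-environment coefficients *p* (similarity among repeated records
of one individual) are iid ``N(0, Sigma_P)``; residuals are unstructured
with one variance per trait.  For hybrid data the additive effect of a
hybrid decomposes as ``a_H = g_E + g_J``, the general-combining-ability
contributions of its two parental-species parents, each with covariance
``Sigma_H. ⊗ (1/2) I``.

Fitting is by a blocked Gibbs sampler with conjugate full conditionals:

* a *parent tier* — fixed coefficients plus the coefficient vectors of all
  individuals that appear as parents — is drawn jointly from its dense
  multivariate-normal full conditional;
* the *terminal tier* (individuals without offspring) is conditionally
  independent given the parent tier, so all terminal coefficient vectors
  are drawn in one vectorised batch (prior ``N(0.5(u_s + u_d), d_i Sigma)``
  with d_i the Mendelian-sampling variance coefficient);
* covariance matrices come from inverse-Wishart full conditionals, with a
  scalar parameter-expansion move (standard-normal working prior) on each
  genetic block, and residual variances from scaled inverse-chi-square.

This decomposition is exact for any pedigree and makes large two-generation
designs (diallels, half-sib trials) cheap: the dense block stays small
while thousands of progeny are updated in vectorised batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .basis import GradientScale, legendre_row, standardize
from .pedigree import (
    UNKNOWN,
    HybridIncidence,
    Pedigree,
    build_A,
    hybrid_incidence,
    mendelian_variance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "MCMCConfig",
    "FitResult",
    "assemble",
    "fit_mcmc",
    "map_estimate",
    "credible_interval",
    "predict_additive",
    "r_squared",
]


class DegenerateDataError(ValueError):
    """Raised when the data carry no usable variation for the model."""


class InsufficientSampleError(ValueError):
    """Raised when too few posterior draws are available for a summary."""


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: polynomial order, traits, random terms, taxon mode.

    A single order M is shared by the site, additive and permanent-
    environment terms.  ``taxon_mode`` is "pure" (own additive effect per
    individual, pedigree covariance) or "hybrid" (per-parent contributions
    from each parental species).
    """

    order: int
    traits: tuple = ("trait",)
    include_permanent: bool = False
    taxon_mode: str = "pure"
    hybrid_taxon: str = "HL"
    species: tuple = ("EL", "JL")
    allow_repeats_without_permanent: bool = False

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if len(self.traits) not in (1, 2):
            raise ValueError("1 or 2 traits supported")
        if self.taxon_mode not in ("pure", "hybrid"):
            raise ValueError("taxon_mode must be 'pure' or 'hybrid'")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def k(self) -> int:
        """Coefficient-vector dimension per random level: traits x (M+1)."""
        return self.n_traits * (self.order + 1)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "traits": list(self.traits),
            "include_permanent": self.include_permanent,
            "taxon_mode": self.taxon_mode,
            "hybrid_taxon": self.hybrid_taxon,
            "species": list(self.species),
        }


@dataclass(frozen=True)
class PriorSpec:
    """Prior configuration.

    Genetic covariance blocks use the zero-belief, zero-scale limit of the
    inverse-Wishart (density ∝ |Sigma|^-(k+1)/2) combined with a scalar
    multiplicative parameter-expansion move whose working parameter has a
    standard-normal prior.  Permanent-environment blocks and residual
    variances carry flat improper priors.
    """

    genetic: str = "parameter-expanded"  # or "jeffreys" (no PX move)
    permanent: str = "flat"
    residual: str = "flat"

    @property
    def use_px(self) -> bool:
        return self.genetic == "parameter-expanded"


#: chain-length presets: (iterations, burn_in, thinning)
PRESETS = {
    "desk": (6_000, 1_000, 10),
    "full-sim": (150_000, 50_000, 1_000),
    "full-real": (5_500_000, 500_000, 5_000),
}


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int
    burn_in: int
    thinning: int
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_draws < 100:
            warnings.warn(
                f"only {self.n_draws} retained draws; >= 100 recommended",
                stacklevel=2,
            )

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "MCMCConfig":
        it, bi, th = PRESETS[name]
        return cls(iterations=it, burn_in=bi, thinning=th, seed=seed)

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# assembly


@dataclass
class AssembledModel:
    """Design matrices and covariance structure ready for the sampler."""

    spec: ModelSpec
    scale: GradientScale
    ped: Pedigree
    y: np.ndarray            # (n_obs,)
    trait_obs: np.ndarray    # (n_obs,) trait index
    cdes: np.ndarray         # (n_obs, k) coefficient-space design row
    W: np.ndarray            # (n_obs, n_beta) fixed design
    sites: list
    # pure mode
    ind_obs: np.ndarray | None = None       # (n_obs,) pedigree index
    parent_idx: np.ndarray | None = None    # pedigree indices of parent tier
    term_idx: np.ndarray | None = None      # pedigree indices of terminal tier
    d: np.ndarray | None = None             # Mendelian variance coefficients
    A_PP: np.ndarray | None = None
    # hybrid mode
    inc: HybridIncidence | None = None
    e_obs: np.ndarray | None = None
    j_obs: np.ndarray | None = None
    # permanent environment
    pe_ids: np.ndarray | None = None        # pedigree indices with records
    pe_obs: np.ndarray | None = None        # (n_obs,) index into pe_ids

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_beta(self) -> int:
        return self.W.shape[1]


def _coeff_row(ell: np.ndarray, trait: int, spec: ModelSpec) -> np.ndarray:
    c = np.zeros(spec.k)
    b = spec.order + 1
    c[trait * b : (trait + 1) * b] = ell
    return c


def assemble(
    data,
    ped: Pedigree,
    spec: ModelSpec,
    scale: GradientScale | None = None,
) -> AssembledModel:
    """Build the design and covariance structure for a phenotype table.

    ``data`` is a long-format table with columns ``tree_id``, ``site``,
    ``covariate`` and one column per trait in ``spec.traits`` (NaN = that
    trait unobserved for the record).  When ``scale`` is None it is computed
    from the covariate range of the data and stored with the model.
    """
    import pandas as pd

    data = pd.DataFrame(data)
    for col in ("tree_id", "site", "covariate"):
        if col not in data.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    for t in spec.traits:
        if t not in data.columns:
            raise ValueError(f"phenotype table lacks trait column {t!r}")

    if scale is None:
        scale = GradientScale.from_data(data["covariate"].to_numpy())

    rec_ind = np.array([ped.index(i) for i in data["tree_id"]])
    if spec.taxon_mode == "pure":
        taxa = np.array([ped.taxon[i] for i in rec_ind])
        if np.any(taxa == spec.hybrid_taxon):
            raise ValueError(
                "records of hybrid individuals passed to a pure-species model; "
                "use taxon_mode='hybrid'"
            )

    # repeated records need the permanent-environment term
    counts = pd.Series(rec_ind).value_counts()
    if (
        not spec.include_permanent
        and not spec.allow_repeats_without_permanent
        and (counts > 1).any()
    ):
        raise ValueError(
            "repeated records per individual require include_permanent=True "
            "(or allow_repeats_without_permanent to override)"
        )

    sites = sorted(data["site"].unique().tolist())
    site_pos = {s: i for i, s in enumerate(sites)}
    b = spec.order + 1
    T = spec.n_traits
    n_beta = len(sites) * b * T

    xs = data["covariate"].to_numpy(dtype=float)
    ells = legendre_row(np.atleast_1d(standardize(xs, scale)), spec.order)

    y_list, trait_list, c_list, w_list, ind_list = [], [], [], [], []
    for r in range(len(data)):
        for ti, tname in enumerate(spec.traits):
            val = data[tname].iloc[r]
            if pd.isna(val):
                continue
            y_list.append(float(val))
            trait_list.append(ti)
            c_list.append(_coeff_row(ells[r], ti, spec))
            w = np.zeros(n_beta)
            col = (ti * len(sites) + site_pos[data["site"].iloc[r]]) * b
            w[col : col + b] = ells[r]
            w_list.append(w)
            ind_list.append(rec_ind[r])
    if not y_list:
        raise DegenerateDataError("no observations after removing missing values")
    y = np.array(y_list)
    if np.var(y) == 0:
        raise DegenerateDataError("zero phenotypic variance")

    m = AssembledModel(
        spec=spec,
        scale=scale,
        ped=ped,
        y=y,
        trait_obs=np.array(trait_list),
        cdes=np.array(c_list),
        W=np.array(w_list),
        sites=sites,
        ind_obs=np.array(ind_list),
    )

    A = build_A(ped)
    if spec.taxon_mode == "pure":
        has_off = ped.has_offspring()
        m.parent_idx = np.flatnonzero(has_off)
        m.term_idx = np.flatnonzero(~has_off)
        m.d = mendelian_variance(ped, A)
        m.A_PP = A.submatrix(m.parent_idx)
        if m.parent_idx.size == 0 and counts.max() == 1 and not spec.include_permanent:
            warnings.warn(
                "all individuals are unrelated founders with single records: "
                "additive and residual variances are only weakly identifiable",
                stacklevel=2,
            )
    else:
        inc = hybrid_incidence(ped, spec.hybrid_taxon, spec.species)
        hyb_pos = {ped.index(h): i for i, h in enumerate(inc.hybrids)}
        e_obs = np.empty(m.n_obs, dtype=int)
        j_obs = np.empty(m.n_obs, dtype=int)
        for r, ind in enumerate(m.ind_obs):
            if ind not in hyb_pos:
                raise ValueError(
                    f"record of non-hybrid individual {ped.ids[ind]!r} in hybrid model"
                )
            h = hyb_pos[ind]
            e_obs[r] = inc.e_of[h]
            j_obs[r] = inc.j_of[h]
        m.inc = inc
        m.e_obs = e_obs
        m.j_obs = j_obs

    if spec.include_permanent:
        pe_ids = np.unique(m.ind_obs)
        pe_pos = {p: i for i, p in enumerate(pe_ids)}
        m.pe_ids = pe_ids
        m.pe_obs = np.array([pe_pos[i] for i in m.ind_obs])
        if pe_ids.size < 2 * spec.k + 2:
            warnings.warn(
                "few individuals relative to the permanent-environment block "
                "size: the flat-prior posterior may be weakly proper",
                stacklevel=2,
            )
    return m


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Retained posterior draws plus the scale/spec needed to use them."""

    spec: ModelSpec
    scale: GradientScale
    config: MCMCConfig
    sites: list
    stored_ids: list            # ids whose coefficient draws are kept
    draws: dict                 # name -> ndarray of draws
    u_mean: np.ndarray | None   # posterior-mean coefficients, all individuals
    p_mean: np.ndarray | None
    ped_ids: list
    model: AssembledModel | None = field(default=None, repr=False)

    @property
    def n_draws(self) -> int:
        return self.draws["sigma2"].shape[0]

    def _stored_pos(self, id_):
        try:
            return self.stored_ids.index(id_)
        except ValueError:
            raise KeyError(
                f"{id_!r} has no stored coefficient draws; refit with "
                "store_effects='all' or use posterior means"
            ) from None

    def coefficient_draws(self, id_, side: str = "sum") -> np.ndarray:
        """Posterior draws (n_draws, k) of an individual's coefficients."""
        if self.spec.taxon_mode == "pure":
            return self.draws["u"][:, self._stored_pos(id_), :]
        # hybrid mode: id may be a parental id (one side) or a hybrid (sum)
        inc = self.model.inc if self.model is not None else None
        e_ids = self.draws["_e_parents"]
        j_ids = self.draws["_j_parents"]
        if side in ("E", "sum") and id_ in e_ids:
            return self.draws["gE"][:, e_ids.index(id_), :]
        if side in ("J", "sum") and id_ in j_ids:
            return self.draws["gJ"][:, j_ids.index(id_), :]
        if inc is not None and id_ in inc.hybrids:
            h = inc.hybrids.index(id_)
            gE = self.draws["gE"][:, inc.e_of[h], :]
            gJ = self.draws["gJ"][:, inc.j_of[h], :]
            if side == "E":
                return gE
            if side == "J":
                return gJ
            return gE + gJ
        raise KeyError(f"no stored draws for {id_!r} (side={side})")


# ---------------------------------------------------------------------------
# sampler


def _inv_psd(Sigma: np.ndarray, floor: float) -> np.ndarray:
    """Inverse of a covariance matrix with eigenvalues floored at ``floor``.

    A flat-tailed prior lets a variance component drift arbitrarily close
    to zero; flooring its eigenvalues at a tiny fraction of the phenotypic
    variance keeps the precision finite without perturbing any draw of
    practical magnitude.
    """
    w, V = np.linalg.eigh(0.5 * (Sigma + Sigma.T))
    w = np.maximum(w, floor)
    return (V / w) @ V.T


def _chol_psd(Prec: np.ndarray) -> np.ndarray:
    """Cholesky with symmetrisation and escalating jitter on the diagonal.

    Near-degenerate fits (residual variance at its floor) push the joint
    precision's dynamic range to the float64 limit; rounding then leaves
    eigenvalues slightly negative.  The jitter only perturbs directions the
    data do not constrain.
    """
    Prec = 0.5 * (Prec + Prec.T)
    scale = np.max(np.diag(Prec))
    jitter = 0.0
    for _ in range(4):
        try:
            return np.linalg.cholesky(Prec + jitter * np.eye(Prec.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100, 1e-12 * scale)
    raise np.linalg.LinAlgError("joint precision matrix not positive definite")


def _batch_mvn(rng, Q: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Draw x_i ~ N(Q_i^{-1} b_i, Q_i^{-1}) for a stack of small precisions.

    Factors Q (not its inverse) so rank-deficient likelihood contributions
    plus a proper prior stay numerically positive definite.
    """
    Q = 0.5 * (Q + np.transpose(Q, (0, 2, 1)))
    try:
        L = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError:
        eps = 1e-10 * np.abs(np.trace(Q, axis1=1, axis2=2)).max()
        Q = Q + eps * np.eye(Q.shape[-1])[None]
        L = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, b[:, :, None])[:, :, 0]
    z = rng.standard_normal(b.shape)
    Lt = np.transpose(L, (0, 2, 1))
    return mean + np.linalg.solve(Lt, z[:, :, None])[:, :, 0]


def _sample_invwishart(rng, df: float, scale_mat: np.ndarray) -> np.ndarray:
    k = scale_mat.shape[0]
    df = max(df, k)  # guard against an improper conditional on tiny data
    jitter = 0.0
    for _ in range(3):
        try:
            draw = stats.invwishart.rvs(
                df=df, scale=scale_mat + jitter * np.eye(k), random_state=rng
            )
            return np.atleast_2d(np.asarray(draw, dtype=float))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * (np.trace(scale_mat) / k + 1e-12))
    raise np.linalg.LinAlgError("inverse-Wishart scale matrix not positive definite")


def fit_mcmc(
    model: AssembledModel,
    cfg: MCMCConfig,
    priors: PriorSpec | None = None,
    *,
    store_effects: str = "parents",
    fix_Sigma_A=None,
    fix_sigma2=None,
    init: dict | None = None,
    update_locations: bool = True,
) -> FitResult:
    """Fit the assembled model by blocked Gibbs sampling.

    ``fix_Sigma_A`` / ``fix_sigma2`` freeze the corresponding updates (used
    for BLUP-equivalence checks); ``store_effects`` is "parents" (default)
    or "all" and controls which individuals' coefficient draws are retained.
    Reproducible: identical config + seed give bit-identical chains.
    """
    priors = priors or PriorSpec()
    spec = model.spec
    rng = np.random.default_rng(cfg.seed)
    k = spec.k
    T = spec.n_traits
    n_obs = model.n_obs
    y = model.y
    W = model.W
    cdes = model.cdes
    trait_obs = model.trait_obs
    n_beta = model.n_beta
    pure = spec.taxon_mode == "pure"

    trait_masks = [trait_obs == t for t in range(T)]
    n_per_trait = np.array([m.sum() for m in trait_masks])

    # ---- precomputations -------------------------------------------------
    if pure:
        q = model.ped.n
        P = model.parent_idx
        Tm = model.term_idx
        nP = P.size
        d = model.d
        sire, dam = model.ped.sire, model.ped.dam
        ppos = {p: i for i, p in enumerate(P)}
        is_term = np.zeros(q, dtype=bool)
        is_term[Tm] = True
        term_obs_mask = is_term[model.ind_obs]

        mdim = n_beta + nP * k
        X_aug = np.zeros((n_obs, mdim))
        X_aug[:, :n_beta] = W
        for r in np.flatnonzero(~term_obs_mask):
            pi = ppos[model.ind_obs[r]]
            X_aug[r, n_beta + pi * k : n_beta + (pi + 1) * k] = cdes[r]
        XtX = np.stack([X_aug[mask].T @ X_aug[mask] for mask in trait_masks])

        # Mendelian coupling of terminals onto parents
        M1 = np.zeros((nP, nP))
        tl_term, tl_ppos, tl_coef = [], [], []
        for t in Tm:
            pars = [p for p in (sire[t], dam[t]) if p != UNKNOWN]
            for a in pars:
                tl_term.append(t)
                tl_ppos.append(ppos[a])
                tl_coef.append(0.5 / d[t])
                for bpar in pars:
                    M1[ppos[a], ppos[bpar]] += 0.25 / d[t]
        tl_term = np.array(tl_term, dtype=int)
        tl_ppos = np.array(tl_ppos, dtype=int)
        tl_coef = np.array(tl_coef, dtype=float)
        A_PP_inv = np.linalg.inv(model.A_PP) if nP else np.zeros((0, 0))
        G_prior = A_PP_inv + M1

        # per-individual likelihood cross-products, per trait
        CC = np.zeros((q, T, k, k))
        outer = cdes[:, :, None] * cdes[:, None, :]
        for t in range(T):
            np.add.at(CC[:, t], model.ind_obs[trait_masks[t]], outer[trait_masks[t]])
        # terminal prior-mean parent links
        t_sire = sire[Tm]
        t_dam = dam[Tm]
    else:
        inc = model.inc
        nE, nJ = len(inc.e_parents), len(inc.j_parents)
        mdim = n_beta + (nE + nJ) * k
        X_aug = np.zeros((n_obs, mdim))
        X_aug[:, :n_beta] = W
        for r in range(n_obs):
            eo, jo = model.e_obs[r], model.j_obs[r]
            X_aug[r, n_beta + eo * k : n_beta + (eo + 1) * k] = cdes[r]
            off = n_beta + (nE + jo) * k
            X_aug[r, off : off + k] = cdes[r]
        XtX = np.stack([X_aug[mask].T @ X_aug[mask] for mask in trait_masks])

    include_pe = spec.include_permanent
    if include_pe:
        n_pe = model.pe_ids.size
        CCpe = np.zeros((n_pe, T, k, k))
        outer_pe = cdes[:, :, None] * cdes[:, None, :]
        for t in range(T):
            np.add.at(CCpe[:, t], model.pe_obs[trait_masks[t]], outer_pe[trait_masks[t]])

    # ---- state -----------------------------------------------------------
    vy = float(np.var(y))
    var_floor = 1e-12 * vy  # keeps precisions finite when a component collapses
    Sigma_A = np.eye(k) * vy / 4 if fix_Sigma_A is None else np.array(fix_Sigma_A, float)
    Sigma_HE = Sigma_A.copy()
    Sigma_HJ = Sigma_A.copy()
    Sigma_P = np.eye(k) * vy / 4
    sigma2 = (
        np.full(T, vy / 2) if fix_sigma2 is None else np.atleast_1d(np.asarray(fix_sigma2, float))
    )
    beta = np.zeros(n_beta)
    if pure:
        u = np.zeros((q, k))
    else:
        gE = np.zeros((nE, k))
        gJ = np.zeros((nJ, k))
    p_eff = np.zeros((n_pe, k)) if include_pe else None
    if init:
        beta = np.array(init.get("beta", beta), float)
        if pure and "u" in init:
            u = np.array(init["u"], float)
        Sigma_A = np.array(init.get("Sigma_A", Sigma_A), float)
        sigma2 = np.atleast_1d(np.asarray(init.get("sigma2", sigma2), float))

    # Parameter expansion (persistent working parameter): the sampler works
    # on u-tilde with covariance Sigma-tilde, the data see lam * u-tilde,
    # and the reported genetic quantities are u = lam*u~, Sigma = lam^2*Sigma~.
    # Keeping lam as state prevents the chain from being absorbed near zero
    # variance: the working effects keep their own scale even when lam ~ 0.
    lam_A = lam_E = lam_J = 1.0

    def perm_part():
        if not include_pe:
            return 0.0
        return np.einsum("rk,rk->r", cdes, p_eff[model.pe_obs])

    def genetic_part():
        if pure:
            return lam_A * np.einsum("rk,rk->r", cdes, u[model.ind_obs])
        return np.einsum(
            "rk,rk->r", cdes, lam_E * gE[model.e_obs] + lam_J * gJ[model.j_obs]
        )

    # ---- storage ---------------------------------------------------------
    if pure:
        if store_effects == "all":
            store_idx = np.arange(q)
        else:
            store_idx = P.copy()
        stored_ids = [model.ped.ids[i] for i in store_idx]
    else:
        stored_ids = list(inc.e_parents) + list(inc.j_parents)
    n_draws = cfg.n_draws
    out = {
        "beta": np.empty((n_draws, n_beta)),
        "sigma2": np.empty((n_draws, T)),
    }
    if pure:
        out["Sigma_A"] = np.empty((n_draws, k, k))
        out["u"] = np.empty((n_draws, store_idx.size, k))
    else:
        out["Sigma_HE"] = np.empty((n_draws, k, k))
        out["Sigma_HJ"] = np.empty((n_draws, k, k))
        out["gE"] = np.empty((n_draws, nE, k))
        out["gJ"] = np.empty((n_draws, nJ, k))
        out["_e_parents"] = list(inc.e_parents)
        out["_j_parents"] = list(inc.j_parents)
    if include_pe:
        out["Sigma_P"] = np.empty((n_draws, k, k))
    u_sum = np.zeros((q, k)) if pure else None
    g_sum = None if pure else (np.zeros((nE, k)), np.zeros((nJ, k)))
    p_sum = np.zeros((n_pe, k)) if include_pe else None

    # ---- iterations ------------------------------------------------------
    stored = 0
    report_every = max(cfg.iterations // 10, 1)
    for it in range(1, cfg.iterations + 1):
        w_obs = 1.0 / sigma2[trait_obs]

        if update_locations:
            Sigma_A_inv = _inv_psd(Sigma_A, var_floor)
            # ---- dense tier: beta (+ parents / GCA contributions)
            # likelihood columns of working genetic effects are scaled by lam
            scol = np.ones(mdim)
            if pure:
                scol[n_beta:] = lam_A
            else:
                scol[n_beta : n_beta + nE * k] = lam_E
                scol[n_beta + nE * k :] = lam_J
            adj = y - perm_part()
            if pure:
                term_gen = np.where(
                    term_obs_mask,
                    lam_A * np.einsum("rk,rk->r", cdes, u[model.ind_obs]),
                    0.0,
                )
                adj = adj - term_gen
            Prec = np.einsum("t,tij->ij", 1.0 / sigma2, XtX) * np.outer(scol, scol)
            rhs = scol * (X_aug.T @ (adj * w_obs))
            if pure:
                if nP:
                    Prec[n_beta:, n_beta:] += np.kron(G_prior, Sigma_A_inv)
                    v = np.zeros((nP, k))
                    np.add.at(v, tl_ppos, u[tl_term] * tl_coef[:, None])
                    rhs[n_beta:] += (v @ Sigma_A_inv).ravel()
            else:
                Sigma_HE_inv = _inv_psd(Sigma_HE, var_floor)
                Sigma_HJ_inv = _inv_psd(Sigma_HJ, var_floor)
                Prec[n_beta : n_beta + nE * k, n_beta : n_beta + nE * k] += np.kron(
                    np.eye(nE), 2.0 * Sigma_HE_inv
                )
                off = n_beta + nE * k
                Prec[off:, off:] += np.kron(np.eye(nJ), 2.0 * Sigma_HJ_inv)
            L = _chol_psd(Prec)
            mean = sla.cho_solve((L, True), rhs)
            z = rng.standard_normal(mdim)
            theta = mean + sla.solve_triangular(L.T, z, lower=False)
            beta = theta[:n_beta]
            if pure:
                if nP:
                    u[P] = theta[n_beta:].reshape(nP, k)
            else:
                gE = theta[n_beta : n_beta + nE * k].reshape(nE, k)
                gJ = theta[n_beta + nE * k :].reshape(nJ, k)

            # ---- terminal tier (pure mode)
            if pure and Tm.size:
                adj2 = y - W @ beta - perm_part()
                Cy = np.zeros((q, k))
                np.add.at(Cy, model.ind_obs, cdes * (adj2 * w_obs)[:, None])
                Q = lam_A**2 * np.einsum("t,ntij->nij", 1.0 / sigma2, CC[Tm])
                Q += Sigma_A_inv[None] / d[Tm, None, None]
                mu = np.zeros((Tm.size, k))
                ms = t_sire != UNKNOWN
                md = t_dam != UNKNOWN
                mu[ms] += 0.5 * u[t_sire[ms]]
                mu[md] += 0.5 * u[t_dam[md]]
                b_vec = lam_A * Cy[Tm] + np.einsum("ij,nj->ni", Sigma_A_inv, mu) / d[Tm, None]
                u[Tm] = _batch_mvn(rng, Q, b_vec)

            # ---- permanent environment tier
            if include_pe:
                adj3 = y - W @ beta - genetic_part()
                Sigma_P_inv = _inv_psd(Sigma_P, var_floor)
                Cp = np.zeros((n_pe, k))
                np.add.at(Cp, model.pe_obs, cdes * (adj3 * w_obs)[:, None])
                Qp = np.einsum("t,ntij->nij", 1.0 / sigma2, CCpe)
                Qp += Sigma_P_inv[None]
                p_eff = _batch_mvn(rng, Qp, Cp)

        # ---- working-parameter updates (parameter expansion)
        if priors.use_px and fix_Sigma_A is None:
            base = y - W @ beta - perm_part()
            if pure:
                g = np.einsum("rk,rk->r", cdes, u[model.ind_obs])
                prec = 1.0 + np.sum(g * g * w_obs)
                lam_A = (
                    np.sum(g * base * w_obs) / prec
                    + rng.standard_normal() / np.sqrt(prec)
                )
            else:
                geh = np.einsum("rk,rk->r", cdes, gE[model.e_obs])
                gjh = np.einsum("rk,rk->r", cdes, gJ[model.j_obs])
                prec = 1.0 + np.sum(geh * geh * w_obs)
                lam_E = (
                    np.sum(geh * (base - lam_J * gjh) * w_obs) / prec
                    + rng.standard_normal() / np.sqrt(prec)
                )
                prec = 1.0 + np.sum(gjh * gjh * w_obs)
                lam_J = (
                    np.sum(gjh * (base - lam_E * geh) * w_obs) / prec
                    + rng.standard_normal() / np.sqrt(prec)
                )

        # ---- covariance updates (working scale)
        if fix_Sigma_A is None:
            if pure:
                mvec = u.copy()
                ks_ = sire != UNKNOWN
                kd_ = dam != UNKNOWN
                mvec[ks_] -= 0.5 * u[sire[ks_]]
                mvec[kd_] -= 0.5 * u[dam[kd_]]
                S = np.einsum("ni,nj->ij", mvec / d[:, None], mvec)
                Sigma_A = _sample_invwishart(rng, q, S)
            else:
                Sigma_HE = _sample_invwishart(rng, nE, 2.0 * gE.T @ gE)
                Sigma_HJ = _sample_invwishart(rng, nJ, 2.0 * gJ.T @ gJ)
        if include_pe:
            Sp = p_eff.T @ p_eff
            Sigma_P = _sample_invwishart(rng, n_pe - k - 1, Sp)
        if fix_sigma2 is None:
            resid = y - W @ beta - genetic_part() - perm_part()
            for t in range(T):
                ss = float(np.sum(resid[trait_masks[t]] ** 2))
                sigma2[t] = max(
                    ss / rng.chisquare(max(n_per_trait[t] - 2, 1)), var_floor
                )

        # ---- store (effective scale: u = lam*u~, Sigma = lam^2*Sigma~)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            out["beta"][stored] = beta
            out["sigma2"][stored] = sigma2
            if pure:
                out["Sigma_A"][stored] = lam_A**2 * Sigma_A
                out["u"][stored] = lam_A * u[store_idx]
            else:
                out["Sigma_HE"][stored] = lam_E**2 * Sigma_HE
                out["Sigma_HJ"][stored] = lam_J**2 * Sigma_HJ
                out["gE"][stored] = lam_E * gE
                out["gJ"][stored] = lam_J * gJ
            if include_pe:
                out["Sigma_P"][stored] = Sigma_P
            if pure:
                u_sum += lam_A * u
            else:
                g_sum[0][:] += lam_E * gE
                g_sum[1][:] += lam_J * gJ
            if include_pe:
                p_sum += p_eff
            stored += 1
        if it % report_every == 0:
            logger.debug("iteration %d / %d", it, cfg.iterations)

    if stored:
        if pure:
            u_mean = u_sum / stored
        else:
            u_mean = None
        p_mean = p_sum / stored if include_pe else None
    else:  # pragma: no cover
        u_mean = p_mean = None

    fit = FitResult(
        spec=spec,
        scale=model.scale,
        config=cfg,
        sites=model.sites,
        stored_ids=stored_ids,
        draws=out,
        u_mean=u_mean,
        p_mean=p_mean,
        ped_ids=list(model.ped.ids),
        model=model,
    )
    if not pure:
        fit.draws["_gE_mean"] = g_sum[0] / max(stored, 1)
        fit.draws["_gJ_mean"] = g_sum[1] / max(stored, 1)
    return fit


# ---------------------------------------------------------------------------
# posterior summaries


def map_estimate(draws, bw_method: str = "silverman") -> float:
    """Maximum a posteriori: mode of a Gaussian KDE over the draws.

    The density is evaluated at the draw points themselves and the argmax
    returned; Silverman's rule sets the bandwidth.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 30:
        raise InsufficientSampleError(f"need >= 30 draws for a MAP, got {draws.size}")
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws, bw_method=bw_method)
    dens = kde(draws)
    return float(draws[np.argmax(dens)])


def credible_interval(draws, level: float = 0.95) -> tuple:
    """Central posterior quantile interval."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise InsufficientSampleError(
            f"need >= 100 draws for a credible interval, got {draws.size}"
        )
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def predict_additive(
    fit: FitResult, id_, x, trait: int = 0, side: str = "sum"
) -> np.ndarray:
    """Posterior draws of an individual's additive value at covariate x.

    Per-draw dot product of the trait's coefficient sub-vector with the
    Legendre row at the standardized x.  For hybrids, ``side`` selects the
    parental contribution ("E", "J") or their sum.
    """
    ell = legendre_row(standardize(x, fit.scale), fit.spec.order)
    b = fit.spec.order + 1
    coef = fit.coefficient_draws(id_, side=side)[:, trait * b : (trait + 1) * b]
    return coef @ ell


def map_coefficients(fit: FitResult, id_, side: str = "sum") -> np.ndarray:
    """Per-scalar MAP of an individual's coefficient vector."""
    draws = fit.coefficient_draws(id_, side=side)
    return np.array([map_estimate(draws[:, j]) for j in range(draws.shape[1])])


def r_squared(fit: FitResult) -> dict:
    """Total R² and per-component variance shares on the training data.

    Fixed coefficients enter at their per-scalar MAP; random effects enter
    at their posterior means (the BLUP-type point predictions).  Component
    share = Var(component predictor) / Var(y).
    """
    m = fit.model
    if m is None:
        raise ValueError("fit has no attached model; refit or reload with data")
    y = m.y
    vy = float(np.var(y))
    if vy == 0:
        raise DegenerateDataError("zero phenotypic variance")
    beta_map = np.array(
        [map_estimate(fit.draws["beta"][:, j]) for j in range(m.n_beta)]
    )
    fixed = m.W @ beta_map
    if fit.spec.taxon_mode == "pure":
        gen = np.einsum("rk,rk->r", m.cdes, fit.u_mean[m.ind_obs])
    else:
        gen = np.einsum(
            "rk,rk->r",
            m.cdes,
            fit.draws["_gE_mean"][m.e_obs] + fit.draws["_gJ_mean"][m.j_obs],
        )
    perm = (
        np.einsum("rk,rk->r", m.cdes, fit.p_mean[m.pe_obs])
        if fit.spec.include_permanent
        else np.zeros_like(y)
    )
    resid = y - fixed - gen - perm
    return {
        "total": 1.0 - float(np.var(resid)) / vy,
        "fixed": float(np.var(fixed)) / vy,
        "additive": float(np.var(gen)) / vy,
        "permanent": float(np.var(perm)) / vy,
    }
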