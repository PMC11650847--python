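"""Single-SNP mixed-model GWAS with fixed variance components.

The scan fits, for each marker i,

    y = X b_i + Z1 u_i + Z2 a_i + w_i v_i + e_i

with a ~ N(0, G sigma2_A) for a VanRaden method-1 genomic relationship matrix
G, optional i.i.d. extra random factors u (batch, litter, herd-year-season,
...), and v_i the fixed allele substitution effect of marker i. Variance
components are estimated once per trait by REML under the null model (no SNP)
and held fixed across the scan, so the covariance V = sigma2_A Z2 G Z2' +
sum_k sigma2_k Z1k Z1k' + sigma2_E I is factored a single time and each SNP
costs one generalized-least-squares update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = 0.454936  # median of the chi-square(1) distribution


# ---------------------------------------------------------------------------
# Genomic relationship matrix


@dataclass
class Grm:
    matrix: np.ndarray
    animal_ids: list[str]
    denominator: float  # 2 * sum p(1-p)
    freq_source: str = "analyzed animals"

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValueError("GRM denominator must be positive")


def compute_grm(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> Grm:
    """VanRaden method 1: G = ZZ' / (2 sum p(1-p)), Z = M - 2P.

    ``freqs`` defaults to the counted-allele frequencies of the analyzed
    animals, in which case the grand sum of G is zero (columns of Z sum to
    zero). Monomorphic markers are rejected.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("GRM requires a complete (imputed) dosage matrix")
    source = "analyzed animals"
    if freqs is None:
        freqs = g.allele_frequencies()
    else:
        freqs = np.asarray(freqs, dtype=float)
        source = "user supplied"
    bad = np.where((freqs <= 0) | (freqs >= 1))[0]
    if bad.size:
        raise ValueError(f"monomorphic marker(s) passed to GRM: {[g.marker_ids[k] for k in bad[:5]]}")
    Z = g.dosages - 2.0 * freqs
    denom = float(2.0 * np.sum(freqs * (1.0 - freqs)))
    return Grm(Z @ Z.T / denom, list(g.animal_ids), denom, source)


# ---------------------------------------------------------------------------
# Design


@dataclass
class GwasDesign:
    """Response, fixed-effect design matrix, and random-factor incidences.

    X always contains an intercept; factor columns are dummy-coded with the
    first level dropped. ``random_factors`` maps factor name -> (n x q)
    incidence matrix; ``Z2`` maps observations to genotype rows.
    """

    trait: str
    y: np.ndarray
    X: np.ndarray
    Z2: np.ndarray
    geno_animal_ids: list[str]
    random_factors: dict[str, np.ndarray] = field(default_factory=dict)
    obs_animal_ids: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design(
    pheno: pd.DataFrame,
    trait: str,
    geno_animal_ids: list[str],
    fixed: list[str] | None = None,
    random: list[str] | None = None,
    animal_col: str = "animal_id",
) -> GwasDesign:
    """Assemble a :class:`GwasDesign` from a phenotype table.

    Rows with a missing response or no matching genotype are dropped; factor
    levels with zero remaining observations are dropped by construction.
    """
    fixed = fixed or []
    random = random or []
    df = pheno.copy()
    df[animal_col] = df[animal_col].astype(str)
    geno_set = {a: k for k, a in enumerate(geno_animal_ids)}
    df = df[df[animal_col].isin(geno_set) & df[trait].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no phenotyped, genotyped animals for trait {trait!r}")
    n = len(df)
    blocks = [np.ones((n, 1))]
    for f in fixed:
        dummies = pd.get_dummies(df[f].astype(str), drop_first=True, dtype=float)
        if dummies.shape[1]:
            blocks.append(dummies.to_numpy())
    X = np.hstack(blocks)
    Z2 = np.zeros((n, len(geno_animal_ids)))
    for i, a in enumerate(df[animal_col]):
        Z2[i, geno_set[a]] = 1.0
    rf = {}
    for f in random:
        dummies = pd.get_dummies(df[f].astype(str), dtype=float)
        rf[f] = dummies.to_numpy()
    return GwasDesign(
        trait=trait,
        y=df[trait].to_numpy(dtype=float),
        X=X,
        Z2=Z2,
        geno_animal_ids=list(geno_animal_ids),
        random_factors=rf,
        obs_animal_ids=list(df[animal_col]),
    )


# ---------------------------------------------------------------------------
# REML


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    extra: dict[str, float] = field(default_factory=dict)
    loglik: float = float("nan")
    converged: bool = True
    boundary: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_e + sum(self.extra.values())

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total

    def to_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a, "sigma2_e": self.sigma2_e, "extra": self.extra,
            "h2": self.h2, "loglik": self.loglik, "converged": self.converged,
            "boundary": self.boundary,
        }


def _reml_loglik(y, X, V) -> float:
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + ypy)


def reml_null(design: GwasDesign, grm: Grm, tol: float = 1e-8, max_iter: int = 400) -> VarianceComponents:
    """REML variance components for the null (no-SNP) model.

    Animal-only models are solved by eigendecomposition of K = Z2 G Z2' and a
    1-D profile-likelihood optimization of the heritability ratio; models with
    extra i.i.d. random factors maximize the restricted log-likelihood over
    log-variances with Nelder-Mead (convergence when successive restricted
    log-likelihoods differ by less than ``tol``). A component pinned within
    1e-6 of total variance of zero is flagged as a boundary estimate.
    """
    y, X = design.y, design.X
    if np.var(y) == 0:
        raise ValueError("response has zero variance; degenerate REML problem")
    K = design.Z2 @ grm.matrix @ design.Z2.T
    n, p = X.shape
    if not design.random_factors:
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0.0, None)
        ys, Xs = U.T @ y, U.T @ X

        def neg_profile(h2: float) -> float:
            gamma = h2 / (1.0 - h2)
            d = gamma * s + 1.0
            Xw = Xs / d[:, None]
            XtDX = Xs.T @ Xw
            beta = np.linalg.solve(XtDX, Xw.T @ ys)
            r = ys - Xs @ beta
            rss = float(np.sum(r * r / d))
            sigma_e = rss / (n - p)
            sign, logdet_x = np.linalg.slogdet(XtDX / sigma_e)
            return 0.5 * (
                (n - p) * np.log(sigma_e) + float(np.sum(np.log(d))) + logdet_x + (n - p)
            )

        res = optimize.minimize_scalar(neg_profile, bounds=(1e-8, 1 - 1e-8), method="bounded",
                                       options={"xatol": 1e-10})
        h2 = float(res.x)
        gamma = h2 / (1.0 - h2)
        d = gamma * s + 1.0
        Xw = Xs / d[:, None]
        beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
        r = ys - Xs @ beta
        sigma_e = float(np.sum(r * r / d)) / (n - p)
        sigma_a = gamma * sigma_e
        vc = VarianceComponents(sigma_a, sigma_e, loglik=-float(res.fun), converged=res.success)
        if h2 < 1e-6:
            vc.boundary.append("sigma2_a")
        return vc

    names = list(design.random_factors)
    ZZ = [design.random_factors[f] @ design.random_factors[f].T for f in names]
    vy = float(np.var(y))
    k = len(names)
    x0 = np.log(np.full(k + 2, vy / (k + 2)))

    last = {"ll": None, "evals": 0}

    def neg_ll(logv):
        V = np.exp(logv[0]) * K + np.exp(logv[-1]) * np.eye(n)
        for j in range(k):
            V += np.exp(logv[1 + j]) * ZZ[j]
        ll = _reml_loglik(y, X, V)
        last["ll"] = ll
        last["evals"] += 1
        return -ll

    res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                            options={"fatol": tol, "xatol": 1e-6, "maxiter": max_iter * (k + 2)})
    v = np.exp(res.x)
    vc = VarianceComponents(
        float(v[0]), float(v[-1]),
        {names[j]: float(v[1 + j]) for j in range(k)},
        loglik=-float(res.fun), converged=bool(res.success),
    )
    if not res.success:
        raise RuntimeError(
            f"REML did not converge in {last['evals']} evaluations; last components {v}"
        )
    total = vc.total
    for name, val in [("sigma2_a", vc.sigma2_a)] + list(vc.extra.items()):
        if val < 1e-6 * total:
            vc.boundary.append(name)
    return vc


def build_covariance(design: GwasDesign, grm: Grm, vc: VarianceComponents) -> np.ndarray:
    """V = sigma2_A Z2 G Z2' + sum_k sigma2_k Z1k Z1k' + sigma2_E I."""
    n = design.n_obs
    V = vc.sigma2_a * (design.Z2 @ grm.matrix @ design.Z2.T) + vc.sigma2_e * np.eye(n)
    for name, Z in design.random_factors.items():
        V += vc.extra[name] * (Z @ Z.T)
    return V


# ---------------------------------------------------------------------------
# Scan


@dataclass
class GwasResult:
    """Per-marker scan results. ``frame`` columns: marker, chrom, pos, maf,
    effect, se, z, p, neglog10p, var_explained (NaN rows = not estimable)."""

    frame: pd.DataFrame
    trait: str
    n_obs: int
    vc: VarianceComponents | None = None

    @property
    def n_estimable(self) -> int:
        return int(self.frame["effect"].notna().sum())

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def snp_scan(
    design: GwasDesign,
    grm: Grm,
    vc: VarianceComponents,
    g: GenotypeMatrix,
    use_t: bool = False,
) -> GwasResult:
    """GLS scan of every marker with variance components held fixed.

    V is Cholesky-factored once; y, X, and all SNP vectors are whitened and the
    SNP effect is the OLS coefficient in the whitened frame after projecting
    out X. Wald z = effect/SE with standard-normal p-values by default
    (``use_t`` switches to a t reference on n - rank(X) - 1 df). Markers
    collinear with the fixed effects (e.g. monomorphic in the analysis set)
    get NaN sentinels.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("scan requires a complete (imputed) dosage matrix")
    if g.animal_ids != design.geno_animal_ids:
        g = g.subset(animals=design.geno_animal_ids)
    V = build_covariance(design, grm, vc)
    c, low = linalg.cho_factor(V, lower=True)
    L = np.tril(c)
    yw = linalg.solve_triangular(L, design.y, lower=True)
    Xw = linalg.solve_triangular(L, design.X, lower=True)
    W = linalg.solve_triangular(L, design.Z2 @ g.dosages, lower=True)
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    RW = W - Q @ (Q.T @ W)
    wtw = np.einsum("ij,ij->j", RW, RW)
    wty = RW.T @ ry
    scale = np.median(wtw[wtw > 0]) if np.any(wtw > 0) else 1.0
    estimable = wtw > 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(estimable, wty / wtw, np.nan)
        se = np.where(estimable, 1.0 / np.sqrt(wtw), np.nan)
        zstat = eff / se
    if use_t:
        df = design.n_obs - np.linalg.matrix_rank(design.X) - 1
        pvals = 2.0 * stats.t.sf(np.abs(zstat), df)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pvals[~estimable] = np.nan
    # MAF over the unique analyzed (genotyped) animals
    analyzed = np.where(design.Z2.sum(axis=0) > 0)[0]
    p_counted = g.dosages[analyzed].mean(axis=0) / 2.0
    maf = np.minimum(p_counted, 1.0 - p_counted)
    frame = pd.DataFrame(
        {
            "marker": g.marker_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "maf": maf,
            "effect": eff,
            "se": se,
            "z": zstat,
            "p": pvals,
            "neglog10p": -np.log10(pvals),
            "var_explained": variance_explained(p_counted, np.where(estimable, eff, np.nan)),
        }
    )
    return GwasResult(frame, design.trait, design.n_obs, vc)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """-log10(alpha / n_tests): the genome-wide significance line."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def variance_explained(p, v, phenotypic_variance: float | None = None):
    """Genetic variance contributed by a marker: 2 p (1-p) v^2.

    Optionally divided by the phenotypic variance to give a fraction.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p) * v**2
    if phenotypic_variance is not None:
        out = out / phenotypic_variance
    return out


def genomic_inflation(res: GwasResult) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ table.

    lambda = median(Wald chi-square) / 0.454936; QQ expected quantiles use
    plotting positions k/(n+1).
    """
    z = res.frame["z"].to_numpy()
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError("need at least 10 estimable markers")
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    obs = np.sort(res.frame["neglog10p"].dropna().to_numpy())[::-1]
    n = obs.size
    expected = -np.log10(np.arange(1, n + 1) / (n + 1))
    qq = pd.DataFrame({"expected_neglog10p": expected, "observed_neglog10p": obs})
    return lam, qq
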