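"""Binomial-logit GLMs, stepwise marker modelling, SNP-wise and windowed
GWAS with contamination filtering and FDR, and the CNV power simulation.

All association tests model the bioassay outcome (resistant = 1,
susceptible = 0) with binomial error and a logit link. Marker codings
follow the conventions of the study design: SNP genotypes enter as the
number of mutant alleles (0/1/2), CNV alleles as presence/absence, and
gene copy number as the number of extra copies. The GLM is fitted by
iteratively reweighted least squares; complete separation is flagged and
the likelihood-ratio p-value is used in place of the (meaningless) Wald
p-value whenever it is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import MISSING, GenotypeSet, SampleTable, filter_sites

logger = logging.getLogger(__name__)

__all__ = [
    "GLMResult",
    "PowerResult",
    "glm_binomial",
    "marker_tests",
    "stepwise_build",
    "StepwiseResult",
    "contamination_filter",
    "snp_gwas",
    "fdr_select",
    "windowed_gwas",
    "cnv_power_simulation",
]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 25
SEPARATION_BOUND = 10.0  # |log-odds| beyond this flags (quasi-)separation
_MU_EPS = 1e-10


@dataclass
class GLMResult:
    terms: list[str]  # includes "intercept" first
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_wald: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool
    p_lrt: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dropped: list[str] = field(default_factory=list)

    def term_p(self, i: int) -> float:
        """Wald p for term i, or the LRT p when separation is flagged."""
        if self.separation and i < len(self.p_lrt) and not np.isnan(self.p_lrt[i]):
            return float(self.p_lrt[i])
        return float(self.p_wald[i])

    def p_for(self, term: str) -> float:
        return self.term_p(self.terms.index(term))


@dataclass
class PowerResult:
    n_sims: int
    alpha: float
    power: float
    mc_se: float
    n_degenerate: int = 0


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _irls(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit logit by IRLS; returns (beta, covariance, converged)."""
    n, p = x.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        xtwx = (x * w[:, None]).T @ x
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(xtwx) @ score
        beta = beta + step
        if np.max(np.abs(step)) < IRLS_TOL:
            converged = True
            break
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
    xtwx = (x * w[:, None]).T @ x
    cov = np.linalg.pinv(xtwx)
    return beta, cov, converged


def _fit_loglik(y: np.ndarray, x: np.ndarray) -> float:
    beta, _, _ = _irls(y, x)
    mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
    return _bernoulli_loglik(y, mu)


def glm_binomial(
    phenotype: np.ndarray, predictors: pd.DataFrame
) -> GLMResult:
    """Binomial-error, logit-link GLM of a binary phenotype.

    Constant predictors are dropped with a warning. When the fit shows
    separation (non-convergence or a coefficient beyond the documented
    bound), per-term likelihood-ratio p-values are computed as fallback.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("phenotype has a single class: model undefined")
    cols, dropped = [], []
    for c in predictors.columns:
        v = predictors[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            dropped.append(c)
            logger.warning("glm_binomial: dropping constant predictor %r", c)
        else:
            cols.append(c)
    if not cols:
        raise ValueError("no varying predictor")
    x = np.column_stack(
        [np.ones(len(y))] + [predictors[c].to_numpy(dtype=float) for c in cols]
    )
    terms = ["intercept"] + cols
    beta, cov, converged = _irls(y, x)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    p_wald = 2.0 * stats.norm.sf(np.abs(z))
    mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
    ll = _bernoulli_loglik(y, mu)
    separation = (not converged) or bool(np.any(np.abs(beta[1:]) > SEPARATION_BOUND))
    p_lrt = np.full(len(terms), np.nan)
    if separation:
        for i in range(1, len(terms)):
            x_red = np.delete(x, i, axis=1)
            ll_red = _fit_loglik(y, x_red)
            lr = max(0.0, 2.0 * (ll - ll_red))
            p_lrt[i] = stats.chi2.sf(lr, df=1)
    return GLMResult(
        terms=terms,
        coefficients=beta,
        std_errors=se,
        p_wald=p_wald,
        log_likelihood=ll,
        converged=converged,
        separation=separation,
        p_lrt=p_lrt,
        dropped=dropped,
    )


def marker_tests(
    st: SampleTable,
    markers: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One single-term GLM per marker column, optional fixed covariates.

    Markers are numeric codings aligned row-wise with ``sample_ids``
    (default: the sample table's order). Constant markers are reported
    with NaN p-values.
    """
    y = st.phenotype_binary(sample_ids)
    rows = []
    for m in markers.columns:
        preds = pd.DataFrame({m: markers[m].to_numpy(dtype=float)})
        if covariates is not None:
            preds = pd.concat(
                [covariates.reset_index(drop=True), preds.reset_index(drop=True)],
                axis=1,
            )
        try:
            res = glm_binomial(y, preds)
        except ValueError:
            rows.append((m, np.nan, np.nan, False))
            continue
        if m in res.terms:
            i = res.terms.index(m)
            rows.append((m, res.coefficients[i], res.term_p(i), res.separation))
        else:
            rows.append((m, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["marker", "coefficient", "p", "separation"])


@dataclass
class StepwiseResult:
    selected: list[str]
    steps: list[tuple[str, float, float]]  # (marker, lrt_p, loglik after)
    final: Optional[GLMResult]


def stepwise_build(
    st: SampleTable,
    markers: pd.DataFrame,
    alpha: float = 0.05,
    sample_ids: Optional[Sequence[str]] = None,
) -> StepwiseResult:
    """Forward stepwise model building from the null model.

    At each step the candidate marker with the smallest likelihood-ratio
    p-value against the current model is added if p < ``alpha``; ties
    break by marker column order. Stops when no remaining marker gives a
    significant improvement.
    """
    y = st.phenotype_binary(sample_ids)
    n = len(y)
    x_cur = np.ones((n, 1))
    ll_cur = _fit_loglik(y, x_cur)
    remaining = list(markers.columns)
    selected: list[str] = []
    steps: list[tuple[str, float, float]] = []
    while remaining:
        best: Optional[tuple[float, int, str, float]] = None
        for order, m in enumerate(remaining):
            v = markers[m].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                continue
            x_try = np.column_stack([x_cur, v])
            ll_try = _fit_loglik(y, x_try)
            lr = max(0.0, 2.0 * (ll_try - ll_cur))
            p = float(stats.chi2.sf(lr, df=1))
            if best is None or (p, order) < (best[0], best[1]):
                best = (p, order, m, ll_try)
        if best is None or best[0] >= alpha:
            break
        p, _, m, ll_new = best
        selected.append(m)
        steps.append((m, p, ll_new))
        x_cur = np.column_stack([x_cur, markers[m].to_numpy(dtype=float)])
        ll_cur = ll_new
        remaining.remove(m)
    final = (
        glm_binomial(y, markers[selected]) if selected else None
    )
    return StepwiseResult(selected=selected, steps=steps, final=final)


def contamination_filter(
    g: GenotypeSet, st: SampleTable, alpha: float = 0.05
) -> np.ndarray:
    """Indices of sites whose genotype dose is NOT correlated with the
    contamination fraction (Spearman p >= ``alpha``).

    Sites correlated with contamination are sequencing artefacts, not
    biology, and are excluded from the GWAS.
    """
    contam = st.contamination(g.samples)
    if np.ptp(contam) == 0:
        return np.arange(g.n_sites)
    keep = []
    for i in range(g.n_sites):
        calls = g.calls[i]
        ok = calls != MISSING
        if ok.sum() < 3 or np.ptp(calls[ok]) == 0:
            keep.append(i)
            continue
        rho, p = stats.spearmanr(calls[ok], contam[ok])
        if not (p < alpha):
            keep.append(i)
    return np.array(keep, dtype=np.int64)


def snp_gwas(
    g: GenotypeSet,
    st: SampleTable,
    min_mac: int = 5,
    contamination_alpha: float = 0.05,
) -> pd.DataFrame:
    """SNP-wise GWAS: keep sites with no missing data and minor allele
    count >= ``min_mac``, drop contamination-correlated sites, then fit a
    binomial-logit GLM of phenotype on allele dose per site."""
    g = filter_sites(g, min_mac=min_mac, max_missing=0.0)
    retained = contamination_filter(g, st, alpha=contamination_alpha)
    g = g.take_sites(retained)
    y = st.phenotype_binary(g.samples)
    ac = g.allele_counts()
    rows = []
    for i, site in enumerate(g.sites):
        dose = g.calls[i].astype(float)
        try:
            res = glm_binomial(y, pd.DataFrame({"dose": dose}))
        except ValueError:
            continue
        if "dose" not in res.terms:
            continue
        j = res.terms.index("dose")
        rows.append(
            (
                site.contig,
                site.pos,
                float(res.coefficients[j]),
                res.term_p(j),
                int(min(ac[i])),
            )
        )
    return pd.DataFrame(rows, columns=["contig", "pos", "coefficient", "p", "mac"])


def fdr_select(p_table: pd.DataFrame, q: float = 0.01) -> pd.DataFrame:
    """Benjamini-Hochberg selection at FDR level ``q``.

    Returns the significant rows with a ``q_value`` column appended.
    """
    if p_table.empty:
        return p_table.assign(q_value=pd.Series(dtype=float))
    reject, q_values, _, _ = multipletests(
        p_table["p"].to_numpy(), alpha=q, method="fdr_bh"
    )
    out = p_table.assign(q_value=q_values)
    return out.loc[reject].reset_index(drop=True)


def windowed_gwas(
    p_table: pd.DataFrame,
    top_n: int = 1000,
    window_bp: int = 100_000,
    min_hits: int = 10,
    offset: int = 0,
) -> pd.DataFrame:
    """Windowed GWAS rule: take the ``top_n`` most significant SNPs (ties
    broken by position), tile each contig with non-overlapping
    ``window_bp`` windows starting at ``offset``, and flag windows with
    at least ``min_hits`` of the top SNPs."""
    if p_table.empty:
        return pd.DataFrame(columns=["contig", "win_start", "win_end", "n_top"])
    ranked = p_table.sort_values(["p", "pos"], kind="mergesort").head(top_n)
    tiles = (ranked["pos"].to_numpy() - 1 - offset) // window_bp
    counts = (
        ranked.assign(tile=tiles)
        .groupby(["contig", "tile"])
        .size()
        .reset_index(name="n_top")
    )
    flagged = counts.loc[counts["n_top"] >= min_hits].copy()
    flagged["win_start"] = flagged["tile"] * window_bp + offset
    flagged["win_end"] = flagged["win_start"] + window_bp
    return (
        flagged[["contig", "win_start", "win_end", "n_top"]]
        .sort_values(["contig", "win_start"])
        .reset_index(drop=True)
    )


def cnv_power_simulation(
    n: int,
    carrier_freq: float,
    mort_wt: float,
    mort_carrier: float,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Monte Carlo power of the carrier presence/absence GLM.

    Each replicate draws carrier status ~ Bernoulli(carrier_freq) for
    ``n`` individuals and death ~ Bernoulli(mort_wt or mort_carrier);
    the binomial-logit GLM of phenotype (alive = 1) on carrier status is
    fitted and the replicate counts as a success when the carrier-term
    p-value (LRT under separation) is below ``alpha``. Replicates with a
    single phenotype class or constant carrier status are degenerate and
    count as non-significant.
    """
    for name, v in (
        ("carrier_freq", carrier_freq),
        ("mort_wt", mort_wt),
        ("mort_carrier", mort_carrier),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_degenerate = 0
    for _ in range(n_sims):
        carrier = (rng.random(n) < carrier_freq).astype(float)
        p_dead = np.where(carrier == 1, mort_carrier, mort_wt)
        alive = (rng.random(n) >= p_dead).astype(float)
        if alive.min() == alive.max() or carrier.min() == carrier.max():
            n_degenerate += 1
            continue
        res = glm_binomial(alive, pd.DataFrame({"carrier": carrier}))
        if res.p_for("carrier") < alpha:
            n_sig += 1
    if n_degenerate:
        logger.info(
            "cnv_power_simulation: %d degenerate replicates counted "
            "non-significant", n_degenerate,
        )
    power = n_sig / n_sims
    return PowerResult(
        n_sims=n_sims,
        alpha=alpha,
        power=power,
        mc_se=math.sqrt(power * (1.0 - power) / n_sims),
        n_degenerate=n_degenerate,
    )
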