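"""Probe-level differential expression and gene-level silencing calls.

The statistical model is the standard two-group microarray contrast:
per probe set, the log2 fold change is ``mean(treated) - mean(control)``
and significance is assessed with an empirical-Bayes moderated
t-statistic.  The probe-wise residual variances s_g^2 (on
d_g = n_t + n_c - 2 degrees of freedom) are assumed to follow a scaled
inverse-chi-square prior with hyperparameters (d0, s0^2); the posterior
variance

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)

shrinks each probe's variance toward the prior, and
t_mod = log_fc / (s~_g * sqrt(1/n_t + 1/n_c)) is referred to a
t-distribution on d0 + d_g degrees of freedom.  The hyperparameters are
estimated by moment matching on z_g = log(s_g^2) using digamma /
trigamma identities, with the trigamma inverse solved by Newton
iteration.

Gene-level calls follow the aggregation rule used throughout the
pipeline: a gene is downregulated when it has at least one
downregulated probe set (FDR <= alpha) and no upregulated one; its
expression value is the mean log2 fold change over its downregulated
probe sets, and the percent reduction 100*(1 - 2^value) is banded into
severity classes strong (>50%), moderate (30-50%) and weak (<30%).
Since only one of the two alleles responds, per-gene reduction is
bounded by 50% in the biological system; the bands reflect that scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .models import GeneModel, ProbeMatrix

logger = logging.getLogger(__name__)

#: d0 above this is reported as +inf (normal reference distribution)
D0_CAP = 1e6


@dataclass(frozen=True)
class ModeratedTParams:
    """Hyperparameters of the variance prior: degrees of freedom and scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


# ---------------------------------------------------------------------------
# baseline filter
# ---------------------------------------------------------------------------

def estimate_silent_baseline(matrix: ProbeMatrix, silent_probe_ids) -> float:
    """Median log2 intensity over all values of probes for normally silent genes.

    Serves as a 'no expression' baseline; probes never exceeding it are
    uninformative.  When no silent-gene probe list is available, skip
    the filter entirely (pass ``baseline=-inf`` downstream) rather than
    inventing a baseline.
    """
    silent = list(silent_probe_ids)
    if not silent:
        raise ValueError(
            "empty silent-probe list: no baseline can be estimated; "
            "skip filtering (use baseline=-inf) instead"
        )
    missing = set(silent) - set(matrix.probe_ids)
    if missing:
        raise ValueError(f"silent probes absent from matrix: {sorted(missing)[:10]}")
    return float(np.median(matrix.values.loc[silent].to_numpy()))


def filter_unexpressed(matrix: ProbeMatrix, baseline: float) -> ProbeMatrix:
    """Drop probes whose value is below ``baseline`` in every sample."""
    if math.isnan(baseline):
        raise ValueError("baseline must not be NaN")
    keep = (matrix.values >= baseline).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("baseline filter removed %d/%d probes", dropped, len(keep))
    return ProbeMatrix(matrix.values.loc[keep], matrix.design)


# ---------------------------------------------------------------------------
# probe-level statistics
# ---------------------------------------------------------------------------

def probe_fold_change(matrix: ProbeMatrix) -> pd.Series:
    """log2 fold change per probe: mean(treated) - mean(control)."""
    matrix.require_replicates(1)
    treated = matrix.group_values("treated").mean(axis=1)
    control = matrix.group_values("control").mean(axis=1)
    return pd.Series(treated - control, index=matrix.probe_ids, name="log_fc")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma target must be positive")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def _fit_variance_prior(s_sq: np.ndarray, d_g: int) -> ModeratedTParams:
    """Moment matching of (d0, s0^2) on z = log(s^2).

    E[z] and Var[z] under the scaled-F model are matched via digamma /
    trigamma; excess variance of z beyond trigamma(d_g/2) determines
    trigamma(d0/2).  Non-positive excess means no evidence of variance
    heterogeneity: d0 = +inf and s0^2 is the harmonic-model mean.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq[s_sq > 0]
    if positive.size == 0:
        raise ValueError("all probe variances are zero: degenerate ensemble")
    if positive.size < s_sq.size:
        # guard against log(0); zero variances carry no scale information
        floor = positive.min()
        s_sq = np.maximum(s_sq, floor)
    z = np.log(s_sq)
    e = z - float(special.digamma(d_g / 2.0)) + math.log(d_g / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d_g / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
        if d0 > D0_CAP:
            d0 = math.inf
    else:
        # no variance heterogeneity beyond chi-square sampling: infinite
        # prior df; the prior scale is the mean observed variance (which,
        # for identical variances, makes s2_post equal every s2)
        d0 = math.inf
        s0_sq = float(s_sq.mean())
    return ModeratedTParams(d0, s0_sq)


def fit_moderated_t(
    matrix: ProbeMatrix, params: ModeratedTParams | None = None
) -> tuple[ModeratedTParams, pd.DataFrame]:
    """Moderated t-statistics and two-sided p-values per probe.

    Hyperparameters are estimated from the probe-variance ensemble
    unless supplied explicitly.  Returns the parameters and a frame
    with columns ``log_fc``, ``s_sq``, ``t_mod``, ``p``.
    """
    matrix.require_replicates(2)
    if len(matrix.probe_ids) < 2 and params is None:
        raise ValueError("need >= 2 probes to estimate the variance prior")
    treated = matrix.group_values("treated")
    control = matrix.group_values("control")
    n_t, n_c = treated.shape[1], control.shape[1]
    d_g = n_t + n_c - 2
    v = 1.0 / n_t + 1.0 / n_c
    log_fc = treated.mean(axis=1) - control.mean(axis=1)
    ss = ((treated - treated.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (control - control.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / d_g
    if params is None:
        params = _fit_variance_prior(s_sq, d_g)
    if math.isinf(params.d0):
        s_tilde_sq = np.full(s_sq.shape, params.s0_sq)
        df = math.inf
    else:
        s_tilde_sq = (params.d0 * params.s0_sq + d_g * s_sq) / (params.d0 + d_g)
        df = params.d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / np.sqrt(s_tilde_sq * v)
    if math.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df)
    frame = pd.DataFrame(
        {"log_fc": log_fc, "s_sq": s_sq, "t_mod": t_mod, "p": p}, index=matrix.probe_ids
    )
    return params, frame


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_probe_status(log_fc, fdr, alpha: float = 0.05) -> pd.Series:
    """Classify probes as down / up / none at the given FDR threshold."""
    log_fc = np.asarray(log_fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    status = np.where(
        (fdr <= alpha) & (log_fc < 0), "down", np.where((fdr <= alpha) & (log_fc > 0), "up", "none")
    )
    return pd.Series(status)


def run_probe_de(
    matrix: ProbeMatrix,
    baseline: float = -math.inf,
    alpha: float = 0.05,
    params: ModeratedTParams | None = None,
) -> tuple[ModeratedTParams, pd.DataFrame]:
    """Full probe-level pipeline: filter, moderated t, BH FDR, status calls."""
    filtered = filter_unexpressed(matrix, baseline)
    params, frame = fit_moderated_t(filtered, params)
    frame = frame.drop(columns=["s_sq"])
    frame["fdr"] = bh_adjust(frame["p"].to_numpy())
    frame["status"] = call_probe_status(frame["log_fc"], frame["fdr"], alpha).values
    frame = frame.rename_axis("probe_set_id").reset_index()
    return params, frame


# ---------------------------------------------------------------------------
# gene-level aggregation
# ---------------------------------------------------------------------------

def severity_class(pct_reduction: float) -> str:
    """Band a percent reduction: strong (>50), moderate ([30, 50]), weak (<30)."""
    if not (0 < pct_reduction < 100):
        raise ValueError(f"pct_reduction must lie in (0, 100), got {pct_reduction}")
    if pct_reduction > 50:
        return "strong"
    if pct_reduction >= 30:
        return "moderate"
    return "weak"


def aggregate_gene_status(genes: list[GeneModel], probe_de: pd.DataFrame) -> pd.DataFrame:
    """Gene-level silencing calls from probe statuses.

    down: >=1 down probe and no up probe; up: mirrored; genes carrying
    both up and down probes are discordant and classed no_change, as
    are genes with no differentially expressed probes.  Genes with no
    probes at all are flagged unscored.
    """
    de = probe_de.set_index("probe_set_id")
    rows = []
    n_discordant = 0
    for gene in genes:
        present = [p for p in gene.probe_sets if p in de.index]
        statuses = de.loc[present, "status"] if present else pd.Series(dtype=str)
        n_down = int((statuses == "down").sum())
        n_up = int((statuses == "up").sum())
        discordant = n_down > 0 and n_up > 0
        n_discordant += discordant
        expr_value = np.nan
        pct = np.nan
        severity = None
        if n_down > 0 and n_up == 0:
            status = "down"
            down_probes = statuses.index[statuses == "down"]
            expr_value = float(de.loc[down_probes, "log_fc"].mean())
            pct = 100.0 * (1.0 - 2.0 ** expr_value)
            severity = severity_class(pct)
        elif n_up > 0 and n_down == 0:
            status = "up"
        else:
            status = "no_change"
        rows.append(
            {
                "gene_id": gene.gene_id,
                "status": status,
                "expr_value": expr_value,
                "pct_reduction": pct,
                "severity": severity,
                "n_probes": len(present),
                "unscored": len(present) == 0,
                "discordant": discordant,
            }
        )
    if n_discordant:
        logger.info("%d gene(s) with both up and down probes classed no_change", n_discordant)
    return pd.DataFrame(rows)


def decile_labels(gene_de: pd.DataFrame, q: int) -> pd.Series:
    """Binary labels: 1 for the q% most strongly silenced genes.

    Ranking key is ``expr_value`` for downregulated genes and 0 for all
    others; exactly ceil(q% * N) genes get label 1, most negative key
    first, ties broken by gene_id for determinism.
    """
    if q not in (10, 20, 30, 40, 50):
        raise ValueError(f"q must be one of 10..50 by tens, got {q}")
    key = np.where(
        (gene_de["status"] == "down").to_numpy(), gene_de["expr_value"].to_numpy(), 0.0
    )
    n = len(gene_de)
    k = math.ceil(q / 100.0 * n)
    order = sorted(range(n), key=lambda i: (key[i], gene_de["gene_id"].iat[i]))
    n_down = int((key < 0).sum())
    if n_down < k:
        logger.warning(
            "only %d downregulated genes for a %d%% label set of %d; "
            "labels assigned by ranking anyway", n_down, q, k,
        )
    labels = np.zeros(n, dtype=int)
    labels[order[:k]] = 1
    return pd.Series(labels, index=gene_de.index, name=f"top{q}")


def regression_response(gene_de: pd.DataFrame) -> pd.Series:
    """Continuous response for regression trees: expr_value for down genes, else 0."""
    key = np.where(
        (gene_de["status"] == "down").to_numpy(), gene_de["expr_value"].to_numpy(), 0.0
    )
    return pd.Series(key, index=gene_de.index, name="response")
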