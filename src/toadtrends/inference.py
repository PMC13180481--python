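"""Trend contrasts, stage-wise multiple-testing correction, and labels.

Two contrasts summarise each fitted trend on the log (linear-predictor)
scale:

begin-end
    ``[f(t_last) - f(t_first)] / (t_last - t_first)`` — the per-year
    multiplicative change between the first and last observed year; the
    headline trend value, and the one classification rests on.
average slope
    the mean of the first derivative of the fitted smooth over the
    observation window; reported alongside, never used for labels.

Uncertainty for both is obtained by parametric simulation from the
multivariate normal over the fitted coefficients. Populations are then
classified through a stage-wise procedure: Benjamini-Hochberg screening on
the omnibus p-values followed by confirmation of the begin-end contrast at
the adjusted level ``alpha * R / m``, controlling the overall FDR of
directional calls. Labels: ``non_significant`` (omnibus not rejected),
``increasing`` / ``decreasing`` (confirmed, by sign of the begin-end
contrast), ``flexible`` (omnibus rejected but begin-end not confirmed —
non-monotonic dynamics). For the log-linear GLM the begin-end contrast and
the omnibus test are the same hypothesis, so screening alone decides and
``flexible`` is unreachable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .trends import FittedTrend


class UnstableFitError(RuntimeError):
    """Coefficient covariance is singular; contrasts are not trustworthy."""


@dataclass
class ContrastResult:
    site_id: str
    begin_end: float
    begin_end_se: float
    begin_end_p: float
    avg_slope: float
    avg_slope_se: float
    avg_slope_p: float


@dataclass
class StagewiseDecision:
    screened: bool
    confirmed: bool
    omnibus_p_adj: float


@dataclass
class TrendLabel:
    site_id: str
    label: Literal["non_significant", "flexible", "increasing", "decreasing"]
    omnibus_p_adj: float
    passed_confirmation: bool
    disappeared: bool
    model_kind: str = ""
    begin_end: float = float("nan")


def compute_contrasts(
    fit: FittedTrend, n_sim: int = 10_000, seed: int = 0
) -> ContrastResult:
    """Begin-end and average-slope contrasts with simulation-based SEs.

    The average slope uses central finite differences (step ``1e-4 x span``)
    on a uniform grid of 201 points. Both contrasts are linear in the
    coefficients, so draws from N(beta, V) give their sampling spread; the
    two-sided p-value uses the simulated SE in a normal reference.
    """
    span = fit.last_year - fit.first_year
    if span <= 0:
        raise ValueError("degenerate time span")
    years = np.array([fit.first_year, fit.last_year], dtype=float)
    Xb = fit.design_matrix(years)
    d_be = (Xb[1] - Xb[0]) / span

    if fit.basis_descriptor["kind"] == "linear":
        # derivative of a + b*t is b exactly; finite differences would only
        # add roundoff and break begin_end == avg_slope == slope
        d_as = d_be
    else:
        grid = np.linspace(fit.first_year, fit.last_year, 201)
        h = 1e-4 * span
        d_as = (fit.design_matrix(grid + h) - fit.design_matrix(grid - h)) / (2 * h)
        d_as = d_as.mean(axis=0)

    beta = fit.coefficients
    cov = np.asarray(fit.coef_covariance, dtype=float)
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / len(beta) * np.eye(len(beta)))
    except np.linalg.LinAlgError as exc:
        raise UnstableFitError(f"site {fit.site_id}: unstable fit") from exc
    rng = np.random.default_rng(seed)
    draws = beta[:, None] + L @ rng.standard_normal((len(beta), n_sim))

    def _summ(d: np.ndarray) -> tuple[float, float, float]:
        est = float(d @ beta)
        sims = d @ draws
        se = float(np.std(sims, ddof=1))
        if se == 0.0:
            return est, 0.0, (1.0 if est == 0.0 else 0.0)
        return est, se, float(2.0 * norm.sf(abs(est) / se))

    be, be_se, be_p = _summ(d_be)
    av, av_se, av_p = _summ(d_as)
    return ContrastResult(fit.site_id, be, be_se, be_p, av, av_se, av_p)


def stagewise_correct(
    omnibus_p: Mapping[str, float],
    contrast_p: Mapping[str, float],
    alpha: float = 0.05,
) -> dict[str, StagewiseDecision]:
    """Two-stage FDR: BH screening on omnibus p, confirmation at alpha*R/m.

    Stage I applies Benjamini-Hochberg to the omnibus p-values at level
    ``alpha``, screening R of m units. Stage II confirms a screened unit
    when its contrast p-value is at most ``alpha * R / m``.
    """
    if set(omnibus_p) != set(contrast_p):
        raise ValueError("omnibus and contrast p-value site sets differ")
    if not omnibus_p:
        return {}
    sites = sorted(omnibus_p)
    po = np.array([omnibus_p[s] for s in sites], dtype=float)
    pc = np.array([contrast_p[s] for s in sites], dtype=float)
    for name, arr in (("omnibus", po), ("contrast", pc)):
        if ((arr < 0) | (arr > 1) | ~np.isfinite(arr)).any():
            raise ValueError(f"{name} p-values must lie in [0, 1]")
    screened, p_adj, *_ = multipletests(po, alpha=alpha, method="fdr_bh")
    m = len(sites)
    r = int(screened.sum())
    level = alpha * r / m
    return {
        s: StagewiseDecision(
            screened=bool(scr),
            confirmed=bool(scr and c <= level),
            omnibus_p_adj=float(adj),
        )
        for s, scr, c, adj in zip(sites, screened, pc, p_adj)
    }


def classify(
    fits: Sequence[FittedTrend],
    contrasts: Sequence[ContrastResult],
    alpha: float = 0.05,
) -> list[TrendLabel]:
    """Assign each population one of the four trend labels.

    GLM and GAM populations are corrected as two separate families: the GAM
    family through the stage-wise screen/confirm procedure, the GLM family
    by BH over its omnibus p-values with direction taken from the sign of
    the slope. ``disappeared`` flags decreasing populations whose last two
    observed counts are zero.
    """
    by_site = {c.site_id: c for c in contrasts}
    if set(by_site) != {f.site_id for f in fits} or len(fits) != len(contrasts):
        raise ValueError("fits and contrasts cover different site sets")
    labels: list[TrendLabel] = []

    gam = [f for f in fits if f.model_kind == "GAM"]
    if gam:
        dec = stagewise_correct(
            {f.site_id: f.omnibus_p for f in gam},
            {f.site_id: by_site[f.site_id].begin_end_p for f in gam},
            alpha=alpha,
        )
        for f in gam:
            d = dec[f.site_id]
            be = by_site[f.site_id].begin_end
            if not d.screened:
                lab = "non_significant"
            elif d.confirmed and be > 0:
                lab = "increasing"
            elif d.confirmed and be < 0:
                lab = "decreasing"
            else:
                lab = "flexible"
            labels.append(
                _make_label(f, lab, d.omnibus_p_adj, d.confirmed, be)
            )

    glm = [f for f in fits if f.model_kind == "GLM"]
    if glm:
        po = np.array([f.omnibus_p for f in glm])
        rej, p_adj, *_ = multipletests(po, alpha=alpha, method="fdr_bh")
        for f, r, adj in zip(glm, rej, p_adj):
            be = by_site[f.site_id].begin_end
            if r and be > 0:
                lab = "increasing"
            elif r and be < 0:
                lab = "decreasing"
            else:
                lab = "non_significant"
            labels.append(_make_label(f, lab, float(adj), bool(r), be))

    order = {f.site_id: i for i, f in enumerate(fits)}
    labels.sort(key=lambda l: order[l.site_id])
    return labels


def _make_label(
    fit: FittedTrend, lab: str, p_adj: float, confirmed: bool, begin_end: float
) -> TrendLabel:
    disappeared = lab == "decreasing" and fit.final_counts == (0, 0)
    return TrendLabel(
        site_id=fit.site_id,
        label=lab,  # type: ignore[arg-type]
        omnibus_p_adj=p_adj,
        passed_confirmation=confirmed,
        disappeared=disappeared,
        model_kind=fit.model_kind,
        begin_end=begin_end,
    )


@dataclass
class LabelSummary:
    table: pd.DataFrame  # label x model_kind counts and percentages
    disappeared_count: int
    begin_end_values: pd.DataFrame  # histogram-ready per-site trend values


LABEL_ORDER = ("increasing", "decreasing", "flexible", "non_significant")


def summarize_labels(labels: Sequence[TrendLabel]) -> LabelSummary:
    """Counts and percentages per label, split by model kind."""
    df = pd.DataFrame(
        [
            {
                "site_id": l.site_id,
                "model_kind": l.model_kind,
                "label": l.label,
                "begin_end": l.begin_end,
                "disappeared": l.disappeared,
            }
            for l in labels
        ],
        columns=["site_id", "model_kind", "label", "begin_end", "disappeared"],
    )
    rows = []
    kinds = sorted(df.model_kind.unique()) if len(df) else []
    for kind in [*kinds, "all"]:
        sub = df if kind == "all" else df[df.model_kind == kind]
        for lab in LABEL_ORDER:
            n = int((sub.label == lab).sum())
            rows.append(
                {
                    "model_kind": kind,
                    "label": lab,
                    "n": n,
                    "percent": 100.0 * n / len(sub) if len(sub) else 0.0,
                }
            )
    return LabelSummary(
        table=pd.DataFrame(rows, columns=["model_kind", "label", "n", "percent"]),
        disappeared_count=int(df.disappeared.sum()) if len(df) else 0,
        begin_end_values=df[["site_id", "model_kind", "begin_end"]],
    )


def labels_to_frame(
    labels: Sequence[TrendLabel], contrasts: Sequence[ContrastResult],
    fits: Sequence[FittedTrend],
) -> pd.DataFrame:
    """Flat per-site results table for CSV export."""
    cmap = {c.site_id: c for c in contrasts}
    fmap = {f.site_id: f for f in fits}
    return pd.DataFrame(
        [
            {
                "site_id": l.site_id,
                "model_kind": l.model_kind,
                "begin_end": cmap[l.site_id].begin_end,
                "begin_end_se": cmap[l.site_id].begin_end_se,
                "begin_end_p": cmap[l.site_id].begin_end_p,
                "avg_slope": cmap[l.site_id].avg_slope,
                "avg_slope_se": cmap[l.site_id].avg_slope_se,
                "omnibus_p": fmap[l.site_id].omnibus_p,
                "omnibus_p_adj": l.omnibus_p_adj,
                "label": l.label,
                "disappeared": l.disappeared,
            }
            for l in labels
        ]
    )
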