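"""Association between population trend values and the surrounding landscape.

Land-use proportions are compositional (they sum to one), so entering all
identity classes in a linear model aliases the intercept. The testing
strategy therefore drops a reference class (agricultural land by default):
the intercept estimates the expected trend in a landscape made entirely of
the reference class and each identity coefficient the effect of replacing
reference-class area with that class. On top of the identity proportions
the model carries three structure terms (Shannon diversity, patch count,
edge length) and one change term (Bray-Curtis distance between map dates),
all standardized.

The decision tree per buffer radius mirrors the workflow the model family
is meant for: (1) F-test of all pairwise identity interactions against the
main-effects model; (2) omnibus F-test of the main-effects model against
intercept-only; (3) per-term post-hoc tests (BH-adjusted) only when an
omnibus rejects; plus a Moran's I spatial-autocorrelation diagnostic on the
residuals with inverse-distance, row-standardized weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .landscape import MERGED_CLASSES

logger = logging.getLogger(__name__)

STRUCTURE_TERMS = ("shannon", "n_patches", "edge_length_m")
CHANGE_TERM = "bray_curtis_change"


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient (compositional aliasing)."""


class DegenerateDesignError(ValueError):
    """No usable columns remain (e.g. every interaction column aliased)."""


@dataclass
class DesignSpec:
    """What enters the linear model for one buffer radius."""

    radius_m: float
    identity_classes: tuple[str, ...] = MERGED_CLASSES
    reference_class: str | None = "agricultural land"
    structure_terms: tuple[str, ...] = STRUCTURE_TERMS
    change_term: str | None = CHANGE_TERM

    def __post_init__(self) -> None:
        if self.reference_class is not None and (
            self.reference_class not in self.identity_classes
        ):
            raise ValueError(
                f"reference class {self.reference_class!r} not among identities"
            )


@dataclass
class MoranResult:
    observed: float
    expected: float
    sd: float
    p: float


@dataclass
class AssociationReport:
    radius_m: float
    n_sites: int
    interaction_F: float
    interaction_df: tuple[int, int]
    interaction_p: float
    omnibus_F: float
    omnibus_df: tuple[int, int]
    omnibus_p: float
    coefficients: pd.DataFrame  # term -> estimate, se, t, p
    moran: MoranResult
    posthoc: dict[str, float] = field(default_factory=dict)


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


# ---------------------------------------------------------------------------
# PCA exploration of raw-class composition


def pca_explore(profile_frame: pd.DataFrame, class_columns: Sequence[str] | None = None,
                n_components: int | None = None) -> PcaResult:
    """PCA on z-transformed class-proportion columns.

    ``profile_frame`` holds one row per site with proportion columns
    (``p_<class>`` by convention, or pass ``class_columns``). Zero-variance
    columns are dropped with a warning. Component signs are fixed by making
    each loading vector's largest-magnitude entry positive.
    """
    if class_columns is None:
        class_columns = [c for c in profile_frame.columns if c.startswith("p_")]
    X = profile_frame[list(class_columns)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 sites")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(class_columns, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    cols = [c for c, k in zip(class_columns, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    index = (
        profile_frame["site_id"]
        if "site_id" in profile_frame
        else profile_frame.index
    )
    return PcaResult(
        scores=pd.DataFrame(scores, columns=names, index=index),
        loadings=pd.DataFrame(loadings.T, index=cols, columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# design construction


def build_design(
    profiles: pd.DataFrame,
    trends: pd.DataFrame,
    spec: DesignSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor matrix and response for one radius.

    Identity proportions stay on their natural [0, 1] scale (keeping the
    reference-class interpretation of the intercept); structure and change
    columns are z-scored. Raises :class:`RankDeficiencyError` naming the
    aliased columns if the design (with intercept) is not full column rank
    — in particular when all identity classes are included.
    """
    prof = profiles[profiles["radius_m"] == spec.radius_m]
    merged = prof.merge(trends[["site_id", "begin_end"]], on="site_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping sites between profiles and trends")
    cols: dict[str, np.ndarray] = {}
    for cls in spec.identity_classes:
        if cls == spec.reference_class:
            continue
        cols[f"p_{cls}"] = merged[f"p_{cls}"].to_numpy(dtype=float)
    terms = list(spec.structure_terms) + (
        [spec.change_term] if spec.change_term else []
    )
    for term in terms:
        v = merged[term].to_numpy(dtype=float)
        s = v.std(ddof=1)
        cols[term] = (v - v.mean()) / s if s > 0 else v - v.mean()
    X = pd.DataFrame(cols, index=merged["site_id"])
    _assert_full_rank(X)
    y = pd.Series(
        merged["begin_end"].to_numpy(dtype=float), index=merged["site_id"],
        name="begin_end",
    )
    return X, y


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Greedy scan: columns that do not increase the rank of [1 | X]."""
    n = len(X)
    basis = np.ones((n, 1))
    aliased = []
    for name in X.columns:
        cand = np.column_stack([basis, X[name].to_numpy(float)])
        if np.linalg.matrix_rank(cand, tol=1e-8 * n) > basis.shape[1]:
            basis = cand
        else:
            aliased.append(name)
    return aliased


def _assert_full_rank(X: pd.DataFrame) -> None:
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(M, tol=1e-8 * len(X)) < M.shape[1]:
        raise RankDeficiencyError(
            "design is rank deficient; aliased columns: "
            f"{_aliased_columns(X)} (unit-sum compositions require dropping "
            "a reference class)"
        )


# ---------------------------------------------------------------------------
# model comparisons


def _ols(X: pd.DataFrame, y: pd.Series):
    return sm.OLS(np.asarray(y, float), sm.add_constant(X.to_numpy(float))).fit()


def test_interactions(
    X: pd.DataFrame, y: pd.Series, spec: DesignSpec
) -> tuple[float, tuple[int, int], float]:
    """F-test of all pairwise identity-proportion interactions.

    Augments the main-effects design with products of the non-reference
    identity columns, dropping any product that is aliased with columns
    already present, and compares the augmented model to the main-effects
    model. Raises :class:`DegenerateDesignError` when no product column
    survives, and :class:`ValueError` when the augmented model would have
    more parameters than observations.
    """
    idcols = [
        f"p_{c}" for c in spec.identity_classes if c != spec.reference_class
    ]
    _assert_full_rank(X)
    n = len(X)
    basis = np.column_stack([np.ones(n), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(basis, tol=1e-8 * n)
    Xa = X.copy()
    for i, a in enumerate(idcols):
        for b in idcols[i + 1 :]:
            prod = X[a].to_numpy(float) * X[b].to_numpy(float)
            cand = np.column_stack([basis, prod])
            if np.linalg.matrix_rank(cand, tol=1e-8 * n) > rank:
                basis = cand
                rank += 1
                Xa[f"{a}:{b}"] = prod
    n_added = Xa.shape[1] - X.shape[1]
    if n_added == 0:
        raise DegenerateDesignError(
            "all identity interaction columns are aliased with the main effects"
        )
    if n <= Xa.shape[1] + 1:
        raise ValueError("augmented interaction model has more parameters than data")
    full = _ols(Xa, y)
    main = _ols(X, y)
    F, p, df_num = full.compare_f_test(main)
    return float(F), (int(df_num), int(full.df_resid)), float(p)


@dataclass
class MainEffectsResult:
    F: float
    df: tuple[int, int]
    p: float
    coefficients: pd.DataFrame
    residuals: np.ndarray
    posthoc: dict[str, float] = field(default_factory=dict)


def test_omnibus_main(
    X: pd.DataFrame, y: pd.Series, alpha: float = 0.05
) -> MainEffectsResult:
    """Omnibus F-test of the main-effects model against intercept-only.

    The per-term coefficient table is always computed; BH-adjusted per-term
    post-hoc p-values are populated only when the omnibus rejects at
    ``alpha`` (the conditional workflow).
    """
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than parameters")
    _assert_full_rank(X)
    yv = np.asarray(y, dtype=float)
    if np.allclose(yv, yv.mean()):
        # response identical to the intercept-only fit: no variance to explain
        res = _ols(X, y)
        coef = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues},
            index=["intercept", *X.columns],
        )
        return MainEffectsResult(
            F=0.0, df=(int(res.df_model), int(res.df_resid)), p=1.0,
            coefficients=coef, residuals=np.asarray(res.resid, float),
        )
    res = _ols(X, y)
    names = ["intercept", *X.columns]
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=names,
    )
    out = MainEffectsResult(
        F=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p=float(res.f_pvalue),
        coefficients=coef,
        residuals=np.asarray(res.resid, dtype=float),
    )
    if out.p <= alpha:
        terms = list(X.columns)
        _, p_adj, *_ = multipletests(
            coef.loc[terms, "p"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        out.posthoc = dict(zip(terms, map(float, p_adj)))
    return out


# ---------------------------------------------------------------------------
# Moran's I residual diagnostic


def moran_residuals(
    residuals: np.ndarray, coords: Sequence[tuple[float, float]]
) -> MoranResult:
    """Moran's I with inverse-distance, row-standardized weights.

    Expected value is exactly -1/(n-1); the standard deviation uses the
    normality assumption; the p-value is two-sided. Duplicate coordinates
    are jittered by 0.5 m (deterministically, along x) with a warning.
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 sites")
    if np.allclose(z, z[0]):
        raise ValueError("residuals have zero variance")
    xy = np.asarray(coords, dtype=float).copy()
    if xy.shape != (n, 2):
        raise ValueError("coords must be n pairs")
    seen: dict[tuple[float, float], int] = {}
    for i in range(n):
        key = (xy[i, 0], xy[i, 1])
        while key in seen:
            xy[i, 0] += 0.5
            key = (xy[i, 0], xy[i, 1])
            logger.warning("duplicate coordinates jittered by 0.5 m (site index %d)", i)
        seen[key] = i
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    W = 1.0 / d
    W /= W.sum(axis=1, keepdims=True)  # row-standardize; S0 == n

    zc = z - z.mean()
    s0 = W.sum()
    I = (n / s0) * (zc @ W @ zc) / (zc @ zc)
    expected = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - expected**2
    sd = float(np.sqrt(var))
    p = float(2.0 * norm.sf(abs((I - expected) / sd)))
    return MoranResult(observed=float(I), expected=expected, sd=sd, p=min(p, 1.0))


# ---------------------------------------------------------------------------
# full workflow


def run_association(
    profiles: pd.DataFrame,
    trends: pd.DataFrame,
    spec: DesignSpec | None = None,
    radii_m: Sequence[float] = (100.0, 500.0, 1000.0),
    alpha: float = 0.05,
) -> tuple[list[AssociationReport], pd.DataFrame, str]:
    """Interaction test -> main-effects omnibus -> conditional post-hoc,
    with a Moran's I residual check, at every buffer radius.

    ``trends`` needs columns ``site_id, begin_end, x_m, y_m``. Returns the
    per-radius reports, an F-table summary frame (radius, F, df, p), and a
    one-line conclusion string.
    """
    reports: list[AssociationReport] = []
    rows = []
    any_signif = False
    for radius in radii_m:
        rspec = (
            DesignSpec(radius_m=float(radius))
            if spec is None
            else DesignSpec(
                radius_m=float(radius),
                identity_classes=spec.identity_classes,
                reference_class=spec.reference_class,
                structure_terms=spec.structure_terms,
                change_term=spec.change_term,
            )
        )
        try:
            X, y = build_design(profiles, trends, rspec)
            try:
                iF, idf, ip = test_interactions(X, y, rspec)
            except ValueError as exc:
                # too few sites for the interaction model: skip that test
                # rather than aborting the whole workflow
                logger.warning("radius %s m: interaction test skipped (%s)", radius, exc)
                iF, idf, ip = float("nan"), (0, 0), float("nan")
            main = test_omnibus_main(X, y, alpha=alpha)
        except Exception as exc:
            raise type(exc)(f"radius {radius} m: {exc}") from exc
        posthoc = dict(main.posthoc)
        if ip <= alpha and not posthoc:
            # interaction omnibus rejected: post-hoc on the main-effect terms
            terms = list(X.columns)
            _, p_adj, *_ = multipletests(
                main.coefficients.loc[terms, "p"].to_numpy(), alpha=alpha,
                method="fdr_bh",
            )
            posthoc = dict(zip(terms, map(float, p_adj)))
        coords = (
            trends.set_index("site_id").loc[y.index, ["x_m", "y_m"]].to_numpy(float)
        )
        moran = moran_residuals(main.residuals, coords)
        any_signif = any_signif or ip <= alpha or main.p <= alpha
        reports.append(
            AssociationReport(
                radius_m=float(radius),
                n_sites=len(y),
                interaction_F=iF,
                interaction_df=idf,
                interaction_p=ip,
                omnibus_F=main.F,
                omnibus_df=main.df,
                omnibus_p=main.p,
                coefficients=main.coefficients,
                moran=moran,
                posthoc=posthoc,
            )
        )
        rows.append(
            {
                "radius_m": float(radius),
                "F": main.F,
                "df_model": main.df[0],
                "df_resid": main.df[1],
                "p": main.p,
            }
        )
    table = pd.DataFrame(rows, columns=["radius_m", "F", "df_model", "df_resid", "p"])
    conclusion = (
        "significant landscape association detected at one or more scales"
        if any_signif
        else "no significant association at any scale"
    )
    return reports, table, conclusion
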