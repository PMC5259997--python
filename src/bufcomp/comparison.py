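"""Statistical comparison of buffer methods.

Two layers of comparison:

1. *Value level* — paired t tests and mean squared error between the BEM
   vectors two buffer methods produce for the same participants.
2. *Association level* — each BEM (standardized to z-scores) enters an
   additive mixed model for each physical-activity outcome with
   socio-demographic covariates as fixed effects and the recruitment cluster
   as a random intercept, fitted by maximum likelihood.  Coefficient pairs
   from two buffer methods are then compared with a z test that treats the
   two estimates as independent — shared participants make the estimates
   positively correlated, so the test is conservative — and tabulated by
   whether each member of the pair is significant at alpha.

The default association term is linear, which is what coefficient-level
comparison requires; a fixed-df regression-spline term is available to probe
curvilinear shape, reporting an omnibus Wald p for the basis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
AGREEMENT_STATUSES = ("both", "neither", "only_method_1", "only_method_2")


class ComparisonError(Exception):
    pass


# ---------------------------------------------------------------------------
# value-level comparison
# ---------------------------------------------------------------------------


@dataclass
class PairComparison:
    """Paired t test + MSE between two methods' vectors of one BEM."""

    bem: str
    method_1: str
    method_2: str
    t: float
    df: int
    p: float
    mse: float
    n: int
    status: str = "ok"  # ok | identical | degenerate


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float, str]:
    """Two-sided paired t test on participant-matched vectors.

    Returns (t, df, p, status); degenerate cases (zero-variance differences)
    are flagged rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ComparisonError("paired t test needs two equal-length 1-d vectors")
    n = len(x)
    if n < 2:
        raise ComparisonError("paired t test needs n >= 2")
    d = x - y
    df = n - 1
    if np.all(d == 0):
        return 0.0, df, 1.0, "identical"
    sd = d.std(ddof=1)
    if sd == 0:
        return math_inf_sign(d.mean()), df, 0.0, "degenerate"
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), "ok"


def math_inf_sign(mean: float) -> float:
    return float("inf") if mean > 0 else float("-inf")


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared element-wise difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ComparisonError("mse needs equal-length vectors")
    return float(np.mean((x - y) ** 2))


def compare_bem_vectors(
    bem_table: pd.DataFrame,
    method_1: str,
    method_2: str,
    bem_columns: tuple[str, ...],
    trim: float = 25.0,
) -> list[PairComparison]:
    """Participant-matched value comparison of every BEM between two methods."""
    out = []
    a = bem_table[(bem_table.method == method_1) & (bem_table.trim == trim)]
    b = bem_table[(bem_table.method == method_2) & (bem_table.trim == trim)]
    a = a.set_index("participant_id").sort_index()
    b = b.set_index("participant_id").sort_index()
    if not a.index.equals(b.index):
        raise ComparisonError("methods cover different participant sets")
    for col in bem_columns:
        x, y = a[col].to_numpy(float), b[col].to_numpy(float)
        t, df, p, status = paired_ttest(x, y)
        out.append(PairComparison(col, method_1, method_2, t, df, p, mse(x, y), len(x), status))
    return out


# ---------------------------------------------------------------------------
# association models
# ---------------------------------------------------------------------------


@dataclass
class AssociationFit:
    """One standardized-BEM coefficient in a mixed model for one outcome."""

    outcome: str
    bem: str
    method: str
    trim: float
    coef: float         # per 1 sd of the BEM; nan for spline terms
    se: float
    p: float
    term: str           # "linear" or "spline(df)"
    converged: bool
    n: int
    stratum: str = "pooled"
    cluster_var: float = float("nan")


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Fixed-df cubic B-spline basis (no intercept column)."""
    degree = 3
    n_inner = df - degree
    if n_inner < 0:
        raise ComparisonError(f"spline df must be >= {degree}")
    inner = np.quantile(x, np.linspace(0, 1, n_inner + 2))[1:-1] if n_inner else np.array([])
    knots = np.r_[[x.min()] * (degree + 1), inner, [x.max()] * (degree + 1)]
    basis = BSpline.design_matrix(np.clip(x, x.min(), x.max()), knots, degree).toarray()
    return basis[:, 1:]  # drop one column: its role is taken by the model intercept


def build_design(
    covariates: pd.DataFrame | None, n: int
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded fixed-effect design for the covariates (no intercept)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0)), []
    num = covariates.select_dtypes(include=[np.number, bool]).astype(float)
    cat = covariates.select_dtypes(exclude=[np.number, bool])
    blocks, names = [], []
    if num.shape[1]:
        blocks.append(num.to_numpy())
        names.extend(num.columns)
    if cat.shape[1]:
        dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        blocks.append(dummies.to_numpy())
        names.extend(dummies.columns)
    mat = np.column_stack(blocks)
    # constant columns (e.g. a stratum covariate inside its own stratum) are
    # collinear with the intercept; drop them
    keep = [j for j in range(mat.shape[1]) if np.ptp(mat[:, j]) > 0]
    return mat[:, keep], [names[j] for j in keep]


def fit_association(
    outcome: np.ndarray,
    bem_z: np.ndarray,
    cluster_ids: np.ndarray,
    covariates: pd.DataFrame | None = None,
    term: str = "linear",
    spline_df: int = 4,
    *,
    outcome_name: str = "outcome",
    bem_name: str = "bem",
    method: str = "",
    trim: float = 25.0,
    stratum: str = "pooled",
) -> AssociationFit:
    """Additive mixed model: outcome ~ f(BEM_z) + covariates + (1 | cluster).

    Fitted by maximum likelihood with a Gaussian error family.  With
    ``term="linear"`` the reported coefficient is the BEM slope per sample sd
    with its Wald p; with ``term="spline"`` the reported p is an omnibus Wald
    test of the whole spline basis and no single slope is reported.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(bem_z, dtype=float)
    groups = np.asarray(cluster_ids)
    n = len(y)
    if len(np.unique(groups)) < 2:
        raise ComparisonError("mixed model needs at least 2 clusters")
    cov_mat, cov_names = build_design(covariates, n)
    if n <= cov_mat.shape[1] + 3:
        raise ComparisonError("too few observations for the fixed-effect design")

    if term == "linear":
        bem_block = x[:, None]
        bem_cols = [1]
    elif term == "spline":
        bem_block = _spline_basis(x, spline_df)
        bem_cols = list(range(1, 1 + bem_block.shape[1]))
    else:
        raise ComparisonError(f"unknown term {term!r}")
    exog = np.column_stack([np.ones(n), bem_block, cov_mat])
    names = ["intercept"] + [f"bem_{i}" for i in range(bem_block.shape[1])] + cov_names

    # fit on a unit-variance response for numerical conditioning; slopes and
    # their ses scale back exactly, p values are invariant
    y_scale = y.std(ddof=1)
    if y_scale == 0 or not np.isfinite(y_scale):
        y_scale = 1.0
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt in ("bfgs", "lbfgs", "powell"):
            try:
                model = sm.MixedLM(y / y_scale, exog, groups=groups)
                res = model.fit(reml=False, method=opt)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if getattr(res, "converged", False) and np.all(np.isfinite(res.bse[bem_cols])):
                break
    if res is None:
        return AssociationFit(
            outcome=outcome_name, bem=bem_name, method=method, trim=trim,
            coef=float("nan"), se=float("nan"), p=float("nan"),
            term=term, converged=False, n=n, stratum=stratum,
        )
    converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.bse[bem_cols]))
    cov_re = np.asarray(res.cov_re)
    cluster_var = float(cov_re[0, 0]) * y_scale**2 if cov_re.size else float("nan")
    if term == "linear":
        coef = float(res.params[1]) * y_scale
        se = float(res.bse[1]) * y_scale
        p = float(res.pvalues[1])
        term_label = "linear"
    else:
        # params include the random-effect variance after the fixed effects
        contrast = np.zeros((len(bem_cols), len(res.params)))
        for r, c in enumerate(bem_cols):
            contrast[r, c] = 1.0
        wald = res.wald_test(contrast, scalar=True)
        coef, se = float("nan"), float("nan")
        p = float(wald.pvalue)
        term_label = f"spline({spline_df})"
    if not converged:
        logger.warning("non-converged fit: %s ~ %s [%s]", outcome_name, bem_name, method)
    return AssociationFit(
        outcome=outcome_name, bem=bem_name, method=method, trim=trim,
        coef=coef, se=se, p=p, term=term_label, converged=converged, n=n,
        stratum=stratum, cluster_var=cluster_var,
    )


# ---------------------------------------------------------------------------
# coefficient comparison and agreement tabulation
# ---------------------------------------------------------------------------


@dataclass
class CoefComparison:
    """z test on a pair of standardized-BEM coefficients from two buffer methods."""

    fit_1: AssociationFit
    fit_2: AssociationFit
    delta: float
    z: float
    p: float
    status: str
    alpha: float = DEFAULT_ALPHA


def agreement_status(p1: float, p2: float, alpha: float = DEFAULT_ALPHA) -> str:
    s1, s2 = p1 < alpha, p2 < alpha
    if s1 and s2:
        return "both"
    if s1:
        return "only_method_1"
    if s2:
        return "only_method_2"
    return "neither"


def compare_coefficients(
    fit_1: AssociationFit, fit_2: AssociationFit, alpha: float = DEFAULT_ALPHA
) -> CoefComparison:
    """Independent-coefficients z test: z = (b1 - b2) / sqrt(se1^2 + se2^2)."""
    for f in (fit_1, fit_2):
        if not f.converged:
            raise ComparisonError(
                f"cannot compare non-converged fit {f.outcome} ~ {f.bem} [{f.method}]"
            )
    if (fit_1.outcome, fit_1.bem, fit_1.stratum) != (fit_2.outcome, fit_2.bem, fit_2.stratum):
        raise ComparisonError("coefficient comparison requires matching outcome/BEM/stratum")
    delta = fit_1.coef - fit_2.coef
    denom = np.sqrt(fit_1.se**2 + fit_2.se**2)
    z = delta / denom if denom > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return CoefComparison(
        fit_1, fit_2, float(delta), float(z), p,
        agreement_status(fit_1.p, fit_2.p, alpha), alpha,
    )


def tabulate_agreement(
    comparisons: list[CoefComparison],
) -> pd.DataFrame:
    """Significance-agreement counts per stratum and method pair.

    ``n_any_significant`` counts pairs where at least one fit has p < alpha;
    ``n_differing`` counts pairs where exactly one does (split by which
    method), with percentages over all model pairs in the cell.
    """
    rows: dict[tuple[str, str], dict] = {}
    for c in comparisons:
        key = (c.fit_1.stratum, f"{c.fit_1.method}_vs_{c.fit_2.method}")
        row = rows.setdefault(
            key,
            {
                "stratum": key[0], "method_pair": key[1], "n_pairs": 0,
                "n_any_significant": 0, "n_both_significant": 0,
                "n_differing": 0, "n_only_method_1": 0, "n_only_method_2": 0,
            },
        )
        row["n_pairs"] += 1
        if c.status != "neither":
            row["n_any_significant"] += 1
        if c.status == "both":
            row["n_both_significant"] += 1
        if c.status in ("only_method_1", "only_method_2"):
            row["n_differing"] += 1
            row[f"n_{c.status}"] += 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["stratum"], r["method_pair"])))
    if len(df):
        df["pct_any_significant"] = 100.0 * df.n_any_significant / df.n_pairs
        df["pct_differing"] = 100.0 * df.n_differing / df.n_pairs
    return df
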