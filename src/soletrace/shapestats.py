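"""Confound-aware statistics on otolith shape descriptors.

Two complementary screens are provided for the shape-versus-covariate
question, both on the model

    response ~ Subunit + Length + Side + Sex + Year

* a redundancy analysis (RDA) of the multivariate shape matrix: multivariate
  least squares on the coded design, partitioning total inertia (sum of
  squared deviations) into constrained and residual parts, with marginal
  permutation F-tests per term (Freedman-Lane: residuals of the reduced model
  are permuted and added back to its fitted values);
* per-index Gaussian linear models with Type III (partial) ANOVA under
  sum-to-zero contrasts, followed by Tukey HSD post hoc comparisons between
  subunits.

``residualize`` removes the confound effects (length, sex, side — never
subunit) from descriptor columns by OLS, for use ahead of assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "RdaModel",
    "rda_fit",
    "rda_permutation_test",
    "fit_index_model",
    "anova_type3",
    "tukey_hsd",
    "residualize",
    "DEFAULT_TERMS",
]

DEFAULT_TERMS = ("Subunit", "Length", "Side", "Sex", "Year")
_FACTOR_TERMS = {"Subunit", "Side", "Sex", "Year"}

_COLMAP = {
    "Subunit": "subunit",
    "Length": "length_cm",
    "Side": "side",
    "Sex": "sex",
    "Year": "year",
}


def _design_frame(design: pd.DataFrame) -> pd.DataFrame:
    """Map a sample/otolith table onto the canonical model columns."""
    out = pd.DataFrame(index=design.index)
    for term, col in _COLMAP.items():
        src = term if term in design.columns else col
        if src in design.columns:
            out[term] = design[src].values
    return out


def _code_term(values: pd.Series, term: str) -> np.ndarray:
    """Dummy-code a factor (drop-first) or return a centered numeric column."""
    if term in _FACTOR_TERMS:
        levels = sorted(pd.unique(values.astype(str)))
        if len(levels) < 2:
            raise ValueError(f"factor {term} has fewer than 2 observed levels")
        arr = np.column_stack(
            [(values.astype(str) == lv).astype(float) for lv in levels[1:]]
        )
        return arr
    return np.asarray(values, dtype=float)[:, None]


@dataclass
class RdaModel:
    """Fitted redundancy analysis: inertia partition and per-term bookkeeping."""

    Y: np.ndarray  # centered responses
    X: np.ndarray  # full coded design (with intercept)
    term_slices: dict[str, slice]
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    df_residual: int
    design: pd.DataFrame


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by QR pivoting
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased or 'unknown'}")


def rda_fit(S: np.ndarray, design: pd.DataFrame, terms=DEFAULT_TERMS) -> RdaModel:
    """Multivariate least squares of the shape matrix on the coded design."""
    Y = np.asarray(S, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    frame = _design_frame(design)
    missing = [t for t in terms if t not in frame.columns]
    if missing:
        raise ValueError(f"design lacks required terms: {missing}")
    if len(frame) != len(Y):
        raise ValueError("rows of S must align with the design table")
    Y = Y - Y.mean(axis=0)
    blocks = [np.ones((len(Y), 1))]
    names = ["Intercept"]
    term_slices: dict[str, slice] = {}
    pos = 1
    for term in terms:
        arr = _code_term(frame[term], term)
        blocks.append(arr)
        names.extend([f"{term}[{j}]" for j in range(arr.shape[1])])
        term_slices[term] = slice(pos, pos + arr.shape[1])
        pos += arr.shape[1]
    X = np.hstack(blocks)
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    resid = Y - fitted
    total = float((Y**2).sum())
    residual = float((resid**2).sum())
    constrained = total - residual
    return RdaModel(
        Y=Y,
        X=X,
        term_slices=term_slices,
        total_inertia=total,
        constrained_inertia=constrained,
        residual_inertia=residual,
        df_residual=len(Y) - X.shape[1],
        design=frame,
    )


def _proj(X: np.ndarray) -> np.ndarray:
    """Hat matrix of X via pseudo-inverse (columns may be collinear-safe)."""
    return X @ np.linalg.pinv(X)


def rda_permutation_test(
    model: RdaModel, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Marginal permutation F-tests for every term of a fitted RDA.

    For term T the pseudo-F is (SS_T / df_T) / (SS_res / df_res) with SS_T the
    drop in residual sum of squares when T is added to the model holding all
    other terms, and SS_res the full-model residual. Null distributions are
    generated by permuting reduced-model residuals (Freedman-Lane);
    p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    import warnings

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    Y = model.Y
    n = len(Y)
    H_full = _proj(model.X)
    R_full = np.eye(n) - H_full
    df_res = model.df_residual
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    rows = []
    for term, sl in model.term_slices.items():
        keep = np.ones(model.X.shape[1], dtype=bool)
        keep[sl] = False
        X_red = model.X[:, keep]
        H_red = _proj(X_red)
        df_term = sl.stop - sl.start
        fit_red = H_red @ Y
        res_red = Y - fit_red
        ss_res_full = float(((R_full @ Y) ** 2).sum())
        ss_term = float(((H_full @ Y) ** 2).sum() - (fit_red**2).sum())
        F_obs = (ss_term / df_term) / (ss_res_full / df_res)
        # permuted response: reduced fit + permuted reduced residuals
        Y_star = fit_red[None, :, :] + res_red[perms]  # (n_perm, n, q)
        full_star = np.einsum("ij,pjq->piq", H_full, Y_star)
        red_star = np.einsum("ij,pjq->piq", H_red, Y_star)
        ss_term_star = (full_star**2).sum(axis=(1, 2)) - (red_star**2).sum(axis=(1, 2))
        ss_res_star = ((Y_star - full_star) ** 2).sum(axis=(1, 2))
        F_star = (ss_term_star / df_term) / (ss_res_star / df_res)
        p = float((1 + np.sum(F_star >= F_obs - 1e-12)) / (1 + n_perm))
        rows.append({"term": term, "df": df_term, "F": F_obs, "p": p})
    return pd.DataFrame(rows)


def fit_index_model(si: pd.Series | np.ndarray, design: pd.DataFrame, terms=DEFAULT_TERMS):
    """OLS of one shape index on the confound model, sum-to-zero contrasts."""
    frame = _design_frame(design).copy()
    missing = [t for t in terms if t not in frame.columns]
    if missing:
        raise ValueError(f"design lacks required terms: {missing}")
    frame["si"] = np.asarray(si, dtype=float)
    parts = []
    for t in terms:
        if t in _FACTOR_TERMS:
            n_levels = frame[t].astype(str).nunique()
            if n_levels < 2:
                raise ValueError(f"factor {t} has fewer than 2 observed levels")
            counts = frame.groupby(frame[t].astype(str))["si"].size()
            if (counts < 2).any():
                raise ValueError(f"factor {t} has levels with < 2 observations")
            parts.append(f"C({t}, Sum)")
        else:
            parts.append(t)
    formula = "si ~ " + " + ".join(parts)
    fit = smf.ols(formula, data=frame).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design in index model")
    return fit


def anova_type3(fit) -> pd.DataFrame:
    """Type III (partial) ANOVA table for a sum-to-zero coded OLS fit."""
    for name in fit.model.exog_names:
        if "C(" in name and "Sum" not in name:
            raise ValueError("Type III ANOVA requires sum-to-zero factor coding")
    table = sm.stats.anova_lm(fit, typ=3)
    table = table.drop(index=[i for i in ("Intercept", "Residual") if i in table.index])
    out = pd.DataFrame(
        {
            "term": [_clean_term(i) for i in table.index],
            "df": table["df"].astype(int).values,
            "F": table["F"].values,
            "p": table["PR(>F)"].values,
        }
    )
    return out.reset_index(drop=True)


def _clean_term(name: str) -> str:
    if name.startswith("C("):
        return name[2:].split(",")[0]
    return name


def tukey_hsd(fit, factor: str = "Subunit", alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons between factor levels, with letters.

    Uses the model's residual mean square and degrees of freedom, raw level
    means of the response, and the harmonic mean of the level sizes for
    unbalanced data (the classical agricolae-style HSD on a fitted model).
    """
    frame = fit.model.data.frame
    if factor not in frame.columns:
        raise ValueError(f"factor {factor} not in model frame")
    y = fit.model.endog
    levels = frame[factor].astype(str)
    names = sorted(levels.unique())
    if len(names) < 2:
        raise ValueError(f"factor {factor} has a single level")
    mse = fit.mse_resid
    df_res = int(fit.df_resid)
    means = {lv: float(np.mean(y[levels.values == lv])) for lv in names}
    sizes = {lv: int(np.sum(levels.values == lv)) for lv in names}
    n_h = len(names) / sum(1.0 / sizes[lv] for lv in names)
    se = np.sqrt(mse / n_h)
    k = len(names)
    rows = []
    sig_pairs = set()
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[names[i]] - means[names[j]]
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_res))
            if p < alpha:
                sig_pairs.add((names[i], names[j]))
            rows.append(
                {
                    "level1": names[i],
                    "level2": names[j],
                    "diff": diff,
                    "q": q,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    letters = _grouping_letters(names, means, sig_pairs)
    table = pd.DataFrame(rows)
    table.attrs["letters"] = letters
    table.attrs["means"] = means
    return table


def _grouping_letters(
    names: list[str], means: dict[str, float], sig_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign compact letter display: levels not significantly different share a letter."""
    ordered = sorted(names, key=lambda lv: -means[lv])

    def differ(a: str, b: str) -> bool:
        return (a, b) in sig_pairs or (b, a) in sig_pairs

    groups: list[set[str]] = []
    for lv in ordered:
        placed = False
        for grp in groups:
            if not any(differ(lv, other) for other in grp):
                grp.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    # drop groups fully contained in another
    groups = [g for g in groups if not any(g < h for h in groups)]
    letters = {lv: "" for lv in names}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lv in sorted(grp, key=lambda x: -means[x]):
            letters[lv] += letter
    return letters


def residualize(
    descriptors: np.ndarray | pd.DataFrame,
    design: pd.DataFrame,
    terms: tuple[str, ...] = ("Length", "Sex", "Side"),
    fit_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Column-wise OLS residuals of descriptors on the named confounds.

    ``Subunit`` is never an allowed confound (it is the signal under study).
    When ``fit_rows`` (boolean mask) is given, confound models are fitted on
    those rows only and applied to all rows — this is the leakage-safe mode
    used inside cross-validation folds. Output columns are centered (on the
    fitting rows).
    """
    if "Subunit" in terms:
        raise ValueError("Subunit may not be residualized out")
    X_desc = np.asarray(descriptors, dtype=float)
    if X_desc.ndim == 1:
        X_desc = X_desc[:, None]
    frame = _design_frame(design)
    missing = [t for t in terms if t not in frame.columns]
    if missing:
        raise ValueError(f"design lacks confound terms: {missing}")
    blocks = [np.ones((len(frame), 1))]
    for t in terms:
        blocks.append(_code_term(frame[t], t))
    X = np.hstack(blocks)
    if fit_rows is None:
        fit_rows = np.ones(len(frame), dtype=bool)
    fit_rows = np.asarray(fit_rows, dtype=bool)
    beta, *_ = np.linalg.lstsq(X[fit_rows], X_desc[fit_rows], rcond=None)
    resid = X_desc - X @ beta
    return resid - resid[fit_rows].mean(axis=0)
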