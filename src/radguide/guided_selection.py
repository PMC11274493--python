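"""Radiomics-guided latent-feature selection and one-vs-rest logistic models.

The core method: CNN latent features are screened by their Pearson
correlation against handcrafted radiomics features on the training cohort —
a latent feature is retained when at least one pair has |r| > 0.4 and a
Bonferroni-corrected p-value < 0.05 — then ranked by the magnitude of
one-vs-rest LASSO coefficients (penalty chosen by inner 5-fold
cross-validation), and the top-k (default 4) are refit in an unpenalized
one-vs-rest logistic model whose per-class odds ratios OR = exp(beta) carry
the effect-size interpretation.

Also implements the baseline radiomics-only model: repeated randomized
80/20 cross-validation with LASSO, features ranked by selection frequency,
the top ``n_select`` (default 35) forming the optimal set.

Bonferroni convention: the default multiplicity ``m`` counts all tested
latent x radiomics pairs (the conservative reading); a per-latent mode is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from radguide.io_core import FeatureTable

DEFAULT_R_THRESH = 0.4
DEFAULT_ALPHA = 0.05
DEFAULT_K = 4
DEFAULT_N_SELECT = 35
DEFAULT_N_ITER = 500

_LASSO_C_GRID = np.logspace(-2, 2, 9)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("constant input")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r and raw two-sided p between columns of x and of y."""
    n = x.shape[0]
    xs = (x - x.mean(0)) / x.std(0)
    ys = (y - y.mean(0)) / y.std(0)
    r = (xs.T @ ys) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScreenResult:
    """All-pairs correlation screen between latent and radiomics features."""

    latent_names: list[str]
    radiomics_names: list[str]
    r: np.ndarray              # (n_latent, n_radiomics)
    p_raw: np.ndarray
    p_corr: np.ndarray
    m: int                     # number of tested pairs (Bonferroni multiplicity)
    r_thresh: float
    alpha: float
    retained: list[str]
    constant_latent: list[str] = field(default_factory=list)
    constant_radiomics: list[str] = field(default_factory=list)
    bonferroni: str = "pairs"

    def pair_frame(self, latents: list[str] | None = None,
                   significant_only: bool = False) -> pd.DataFrame:
        """Tidy (latent, radiomics, r, p_raw, p_corr) rows, |r| descending."""
        which = latents if latents is not None else self.latent_names
        idx = [self.latent_names.index(l) for l in which]
        rows = []
        for i, lname in zip(idx, which):
            sel = np.ones(len(self.radiomics_names), dtype=bool)
            if significant_only:
                sel = self.p_corr[i] < self.alpha
            for j in np.flatnonzero(sel):
                rows.append({
                    "latent": lname,
                    "radiomics": self.radiomics_names[j],
                    "r": self.r[i, j],
                    "p_raw": self.p_raw[i, j],
                    "p_corr": self.p_corr[i, j],
                })
        df = pd.DataFrame(rows, columns=["latent", "radiomics", "r", "p_raw", "p_corr"])
        return df.reindex(df["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)

    def max_abs_r(self) -> pd.Series:
        """Strongest |r| per latent (used as a deterministic tie-break)."""
        return pd.Series(np.abs(self.r).max(axis=1), index=self.latent_names)


def correlation_screen(latent_table: FeatureTable, radiomics_table: FeatureTable,
                       r_thresh: float = DEFAULT_R_THRESH,
                       alpha: float = DEFAULT_ALPHA,
                       bonferroni: str = "pairs") -> CorrelationScreenResult:
    """Screen latent features by correlation with radiomics features.

    Constant features on the training cohort are excluded from the screen
    (and from the multiplicity count m). A latent feature is retained iff
    some pair satisfies |r| > r_thresh AND Bonferroni-corrected p < alpha.
    """
    if list(latent_table.subjects) != list(radiomics_table.subjects):
        raise ValueError("latent and radiomics tables cover different subjects")
    if bonferroni not in ("pairs", "per_latent"):
        raise ValueError("bonferroni mode must be 'pairs' or 'per_latent'")
    lx = latent_table.df
    rx = radiomics_table.df
    const_l = [c for c in lx.columns if lx[c].std() == 0]
    const_r = [c for c in rx.columns if rx[c].std() == 0]
    lx = lx.drop(columns=const_l)
    rx = rx.drop(columns=const_r)
    r, p_raw = _pearson_matrix(lx.to_numpy(), rx.to_numpy())
    if bonferroni == "pairs":
        m = r.size
    else:
        m = r.shape[1]
    p_corr = np.minimum(p_raw * m, 1.0)
    hit = (np.abs(r) > r_thresh) & (p_corr < alpha)
    retained = [lx.columns[i] for i in np.flatnonzero(hit.any(axis=1))]
    return CorrelationScreenResult(
        latent_names=list(lx.columns), radiomics_names=list(rx.columns),
        r=r, p_raw=p_raw, p_corr=p_corr, m=int(m), r_thresh=r_thresh,
        alpha=alpha, retained=retained, constant_latent=const_l,
        constant_radiomics=const_r, bonferroni=bonferroni,
    )


# ---------------------------------------------------------------------------
# LASSO ranking
# ---------------------------------------------------------------------------

def _choose_l1_penalty(x: np.ndarray, y: np.ndarray, classes: np.ndarray,
                       seed: int, n_folds: int = 5,
                       c_grid: np.ndarray = _LASSO_C_GRID) -> float:
    """Inner-CV choice of the L1 penalty by one-vs-rest deviance."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(c_grid))
    for tr_idx, va_idx in cv.split(x, y):
        for ci, c in enumerate(c_grid):
            dev = 0.0
            for cls in classes:
                yb_tr = (y[tr_idx] == cls).astype(int)
                yb_va = (y[va_idx] == cls).astype(int)
                if yb_tr.min() == yb_tr.max():  # degenerate fold: skip class
                    continue
                clf = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                         max_iter=500, random_state=0)
                clf.fit(x[tr_idx], yb_tr)
                p = np.clip(clf.predict_proba(x[va_idx])[:, 1], 1e-12, 1 - 1e-12)
                dev += -np.mean(yb_va * np.log(p) + (1 - yb_va) * np.log(1 - p))
            scores[ci] += dev
    return float(c_grid[int(np.argmin(scores))])


def _ovr_l1_coefs(x: np.ndarray, y: np.ndarray, classes: np.ndarray,
                  c: float) -> np.ndarray:
    """(n_classes, n_features) L1 one-vs-rest coefficients."""
    coefs = np.zeros((len(classes), x.shape[1]))
    for k, cls in enumerate(classes):
        yb = (y == cls).astype(int)
        clf = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                 max_iter=500, random_state=0)
        clf.fit(x, yb)
        coefs[k] = clf.coef_[0]
    return coefs


def lasso_rank(features: FeatureTable, labels: list[str], seed: int = 0,
               n_folds: int = 5, c_grid: np.ndarray = _LASSO_C_GRID,
               tie_break: pd.Series | None = None) -> pd.DataFrame:
    """Rank features by max one-vs-rest |LASSO coefficient|.

    Features are expected Z-scored. Returns a frame sorted by descending
    score with deterministic tie-breaking (larger ``tie_break`` value, e.g.
    the screen's max |r|, then lexicographic name).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    x = features.values
    c = _choose_l1_penalty(x, y, classes, seed, n_folds, c_grid)
    coefs = _ovr_l1_coefs(x, y, classes, c)
    score = np.abs(coefs).max(axis=0)
    tb = tie_break.reindex(features.features).fillna(0.0).to_numpy() \
        if tie_break is not None else np.zeros_like(score)
    df = pd.DataFrame({
        "feature": features.features,
        "score": score,
        "tie_break": tb,
    })
    df = df.sort_values(["score", "tie_break", "feature"],
                        ascending=[False, False, True],
                        kind="mergesort").reset_index(drop=True)
    df.attrs["chosen_C"] = c
    return df


# ---------------------------------------------------------------------------
# guided model
# ---------------------------------------------------------------------------

@dataclass
class ClassCoefficients:
    """Unpenalized one-vs-rest logistic fit for one class."""

    class_label: str
    intercept: float
    beta: pd.Series
    se: pd.Series
    odds_ratio: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_value: pd.Series
    ridge_fallback: bool = False


@dataclass
class GuidedModel:
    """Top-k retained latent features and their one-vs-rest logistic model."""

    features: list[str]
    classes: list[str]
    per_class: dict[str, ClassCoefficients]
    ranking: pd.DataFrame
    r_thresh: float
    alpha: float
    #: optional Z-score parameters (feature -> (mean, sd)) for raw tables
    zscore: dict[str, tuple[float, float]] | None = None

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            cc = self.per_class[cls]
            for f in self.features:
                rows.append({
                    "feature": f, "class": cls, "beta": cc.beta[f],
                    "se": cc.se[f], "odds_ratio": cc.odds_ratio[f],
                    "ci_low": cc.ci_low[f], "ci_high": cc.ci_high[f],
                    "p_value": cc.p_value[f],
                })
        return pd.DataFrame(rows)


def odds_ratio(beta: float) -> float:
    return float(np.exp(beta))


def wald_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _fit_binary_logit(x: np.ndarray, yb: np.ndarray,
                      ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray, bool]:
    """Unpenalized binary logistic fit with Wald standard errors.

    The ordinary fit goes through statsmodels; (quasi-)separation — a
    failed fit or runaway coefficients — falls back to a weakly ridge-
    penalized Newton fit with SEs from the penalized information matrix.
    Returns (params [intercept + betas], standard errors, used_ridge).
    """
    if ridge == 0:
        import statsmodels.api as sm

        xd = sm.add_constant(x, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yb, xd).fit(disp=0, maxiter=100)
            params = np.asarray(fit.params, dtype=np.float64)
            se = np.asarray(fit.bse, dtype=np.float64)
            if (fit.mle_retvals.get("converged", False)
                    and np.max(np.abs(params)) <= 30
                    and np.all(np.isfinite(se))):
                return params, se, False
        except Exception:
            pass
        warnings.warn("separation detected; refitting with ridge penalty",
                      RuntimeWarning, stacklevel=2)
        return _fit_binary_logit(x, yb, ridge=1.0)

    xd = np.column_stack([np.ones(len(x)), x])
    n_par = xd.shape[1]
    beta = np.zeros(n_par)
    lam = ridge
    used_ridge = ridge > 0
    for it in range(100):
        eta = xd @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = xd.T @ (yb - p) - lam * np.r_[0.0, beta[1:]]
        h = xd.T @ (xd * w[:, None]) + lam * np.diag(np.r_[0.0, np.ones(n_par - 1)])
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = xd @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    h = xd.T @ (xd * w[:, None]) + lam * np.diag(np.r_[0.0, np.ones(n_par - 1)])
    cov = np.linalg.pinv(h)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, se, used_ridge


def fit_guided_model(latent_table: FeatureTable, labels: list[str],
                     screen_result: CorrelationScreenResult,
                     k: int = DEFAULT_K, seed: int = 0) -> GuidedModel:
    """Rank retained latents by LASSO, keep top-k, fit unpenalized OVR LR.

    ``latent_table`` must be Z-scored with training-cohort parameters; the
    reported coefficients are therefore standardized. OR = exp(beta), Wald
    95% CI = exp(beta +/- 1.96 SE).
    """
    retained = [f for f in screen_result.retained if f in latent_table.df.columns]
    if len(retained) < k:
        raise ValueError(
            f"screen retained only {len(retained)} latent feature(s); "
            f"lower k (requested {k})")
    sub = FeatureTable(latent_table.df[retained])
    ranking = lasso_rank(sub, labels, seed=seed,
                         tie_break=screen_result.max_abs_r())
    if (ranking["score"] > 0).sum() == 0:
        # all-zero coefficients (penalty -> infinity): fall back to screen order
        ranking = ranking.sort_values(["tie_break", "feature"],
                                      ascending=[False, True],
                                      kind="mergesort").reset_index(drop=True)
    top_k = list(ranking["feature"].iloc[:k])
    x = latent_table.df[top_k].to_numpy()
    y = np.asarray(labels)
    classes = sorted(set(labels))
    per_class = {}
    for cls in classes:
        yb = (y == cls).astype(float)
        params, se, used_ridge = _fit_binary_logit(x, yb)
        beta = pd.Series(params[1:], index=top_k)
        se_s = pd.Series(se[1:], index=top_k)
        orr = np.exp(beta)
        ci_lo = np.exp(beta - 1.959963984540054 * se_s)
        ci_hi = np.exp(beta + 1.959963984540054 * se_s)
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.where(se_s > 0, beta / se_s, 0.0)
        pval = pd.Series(2.0 * stats.norm.sf(np.abs(zstat)), index=top_k)
        per_class[cls] = ClassCoefficients(
            class_label=cls, intercept=float(params[0]), beta=beta, se=se_s,
            odds_ratio=orr, ci_low=ci_lo, ci_high=ci_hi, p_value=pval,
            ridge_fallback=used_ridge,
        )
    return GuidedModel(features=top_k, classes=classes, per_class=per_class,
                       ranking=ranking, r_thresh=screen_result.r_thresh,
                       alpha=screen_result.alpha)


def predict(model: GuidedModel, table: FeatureTable) -> tuple[list[str], pd.DataFrame]:
    """One-vs-rest normalized class probabilities and argmax labels."""
    missing = [f for f in model.features if f not in table.df.columns]
    if missing:
        raise ValueError(f"table missing model feature(s): {missing}")
    x = table.df[model.features].to_numpy()
    scores = np.zeros((len(x), len(model.classes)))
    for j, cls in enumerate(model.classes):
        cc = model.per_class[cls]
        eta = cc.intercept + x @ cc.beta.to_numpy()
        scores[:, j] = 1.0 / (1.0 + np.exp(-eta))
    probs = scores / scores.sum(axis=1, keepdims=True)
    labels = [model.classes[i] for i in probs.argmax(axis=1)]
    pdf = pd.DataFrame(probs, columns=model.classes, index=table.subjects)
    return labels, pdf


# ---------------------------------------------------------------------------
# baseline radiomics model
# ---------------------------------------------------------------------------

@dataclass
class BaselineRadiomicsModel:
    selected: list[str]
    frequencies: pd.Series     # selection frequency over iterations, all features
    coefficients: pd.DataFrame  # final OVR refit on the selected set
    classes: list[str]
    chosen_C: float
    n_iter: int


def baseline_radiomics_model(radiomics_table: FeatureTable, labels: list[str],
                             n_select: int = DEFAULT_N_SELECT,
                             n_iter: int = DEFAULT_N_ITER,
                             seed: int = 0) -> BaselineRadiomicsModel:
    """Randomized-CV LASSO selection of the optimal radiomics feature set.

    Per iteration a stratified random 80/20 split is drawn, one-vs-rest
    LASSO (penalty fixed by 5-fold CV on the full training table) is fitted
    on the 80% and features with any nonzero coefficient are recorded. The
    optimal set is the ``n_select`` features with the highest selection
    frequency (ties broken lexicographically); a one-vs-rest logistic model
    is refit on the full table restricted to that set.
    """
    y = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    x = radiomics_table.values
    names = np.asarray(radiomics_table.features)
    c = _choose_l1_penalty(x, y, np.asarray(classes), seed)
    counts = np.zeros(len(names))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    for it in range(n_iter):
        rs = int(rng.integers(0, 2 ** 31 - 1))
        idx_tr, _ = train_test_split(np.arange(len(y)), test_size=0.2,
                                     stratify=y, random_state=rs)
        coefs = _ovr_l1_coefs(x[idx_tr], y[idx_tr], np.asarray(classes), c)
        counts += (np.abs(coefs) > 0).any(axis=0)
    freq = pd.Series(counts / n_iter, index=names)
    ever = freq[freq > 0]
    if n_select > len(ever):
        raise ValueError(
            f"n_select={n_select} exceeds the {len(ever)} features ever selected")
    order = freq.sort_values(ascending=False, kind="mergesort")
    # deterministic tie handling: frequency desc, then name
    tie_sorted = sorted(order.index, key=lambda f: (-order[f], f))
    selected = list(tie_sorted[:n_select])
    xf = radiomics_table.df[selected].to_numpy()
    coef_rows = []
    for cls in classes:
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(xf, (y == cls).astype(int))
        coef_rows.append(pd.Series(clf.coef_[0], index=selected, name=cls))
    coefficients = pd.DataFrame(coef_rows)
    return BaselineRadiomicsModel(selected=selected, frequencies=freq,
                                  coefficients=coefficients, classes=classes,
                                  chosen_C=c, n_iter=n_iter)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: GuidedModel, path) -> None:
    """Write a GuidedModel to JSON (features, coefficients, ORs, Z-params)."""
    import json
    from pathlib import Path

    payload = {
        "features": model.features,
        "classes": model.classes,
        "r_thresh": model.r_thresh,
        "alpha": model.alpha,
        "zscore": model.zscore,
        "ranking": model.ranking.to_dict(orient="list"),
        "per_class": {
            cls: {
                "intercept": cc.intercept,
                "beta": cc.beta.to_dict(),
                "se": cc.se.to_dict(),
                "odds_ratio": cc.odds_ratio.to_dict(),
                "ci_low": cc.ci_low.to_dict(),
                "ci_high": cc.ci_high.to_dict(),
                "p_value": cc.p_value.to_dict(),
                "ridge_fallback": cc.ridge_fallback,
            }
            for cls, cc in model.per_class.items()
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))


def load_model(path) -> GuidedModel:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    feats = payload["features"]
    per_class = {}
    for cls, d in payload["per_class"].items():
        per_class[cls] = ClassCoefficients(
            class_label=cls,
            intercept=float(d["intercept"]),
            beta=pd.Series(d["beta"]).reindex(feats),
            se=pd.Series(d["se"]).reindex(feats),
            odds_ratio=pd.Series(d["odds_ratio"]).reindex(feats),
            ci_low=pd.Series(d["ci_low"]).reindex(feats),
            ci_high=pd.Series(d["ci_high"]).reindex(feats),
            p_value=pd.Series(d["p_value"]).reindex(feats),
            ridge_fallback=bool(d.get("ridge_fallback", False)),
        )
    zscore = payload.get("zscore")
    if zscore is not None:
        zscore = {k: (float(v[0]), float(v[1])) for k, v in zscore.items()}
    return GuidedModel(
        features=feats, classes=payload["classes"], per_class=per_class,
        ranking=pd.DataFrame(payload["ranking"]),
        r_thresh=float(payload["r_thresh"]), alpha=float(payload["alpha"]),
        zscore=zscore,
    )
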