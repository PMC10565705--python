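"""DoG-basis regression family, width grid search, and BIC model comparison.

Serial-dependence bias curves follow the shape of the first derivative of
a Gaussian (DoG): the adjustment error y as a function of the orientation
difference Δ to a prior stimulus rises to a peak near Δ ≈ σ and decays for
larger Δ.  Rather than fitting a single DoG, the analysis fits a *family*
of linear regression models on pooled single-trial data and compares them
by BIC:

    Δ0      y = a
    Δ1      y = a + b·f(Δ; w)
    Δ2      y = a + b₁·f(Δ; w₁) + b₂·f(Δ; w₂),  w₂ ≥ 2·w₁
    Δ1×loc  y = a + b₁·f(Δ; w) + b₂·f(Δ; w)·Loc
    Δ2×loc  y = a + b₁·f(Δ; w₁) + b₂·f(Δ; w₂) + b₃·f(Δ; w₁)·Loc + b₄·f(Δ; w₂)·Loc

with basis f(Δ; w) = Δ·exp(−Δ²/(2w²)), Loc a dummy (random = 0, fixed = 1),
and each width searched on a grid (default 10°–80° in 1° steps), keeping
the assignment with the highest r².  The two components of Δ2 share one
Δ but have distinct widths, letting opposite-signed coefficients capture
a mixture of attraction at small Δ and repulsion at large Δ.

Two-component fits constrain the width pair to w₂ ≥ 2·w₁ (an octave of
separation).  Pairs of similar widths span a nearly collinear column
pair whose difference mimics a width-derivative; an unconstrained joint
search routinely lands on such pairs with huge opposite-signed
coefficients, fitting the *curve* fine but making per-component peak
biases meaningless.  Requiring scale separation — the repulsive tail
lives at distinctly larger Δ than the attractive core — keeps the
components identifiable while still nesting every single-component fit
(either coefficient may be zero).

ΔBIC is reported on the convention used for the family: the worst model
(largest BIC) gets 0 and larger values are better; differences ≥2 count
as positive and ≥6 as strong evidence.

The grid search runs on closed-form normal equations over precomputed
Gram matrices (one pass over the data per family), and the winning width
assignment is refit with statsmodels OLS, which supplies the reported
coefficients and standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DEFAULT_WIDTH_GRID",
    "MODEL_NAMES",
    "ModelSpec",
    "FitResult",
    "ComparisonTable",
    "dog_basis",
    "fit_dog_model",
    "fit_model_family",
    "bic",
    "compare_models",
    "peak_bias",
    "split_by_similarity",
    "compare_coefficients",
    "smooth_curve",
    "prepare_predictor",
]

DEFAULT_WIDTH_GRID = np.arange(10.0, 81.0, 1.0)

MODEL_NAMES = ("d0", "d1", "d2", "d1xloc", "d2xloc")
_DISPLAY = {"d0": "Δ0", "d1": "Δ1", "d2": "Δ2", "d1xloc": "Δ1×loc", "d2xloc": "Δ2×loc"}


@dataclass(frozen=True)
class ModelSpec:
    """One member of the serial-dependence model family."""

    name: str
    n_components: int
    location_interaction: bool

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        name = name.lower().replace("δ", "d").replace("*", "x").replace("×", "x")
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
        n_comp = {"d0": 0, "d1": 1, "d2": 2, "d1xloc": 1, "d2xloc": 2}[name]
        return cls(name=name, n_components=n_comp, location_interaction="xloc" in name)

    @property
    def display_name(self) -> str:
        return _DISPLAY[self.name]

    def term_names(self) -> list[str]:
        terms = ["intercept"]
        terms += [f"delta{i + 1}" for i in range(self.n_components)]
        if self.location_interaction:
            terms += [f"delta{i + 1}:loc" for i in range(self.n_components)]
        return terms


MODEL_FAMILY = tuple(ModelSpec.from_name(n) for n in MODEL_NAMES)


def dog_basis(delta, width: float):
    """DoG regression basis ``Δ·exp(−Δ²/(2·width²))``.

    Odd in Δ, with extrema at Δ = ±width of magnitude ``width·e^{−½}``.
    Unlike the generative kernel this is *not* peak-normalised: regression
    coefficients stay on the natural scale and :func:`peak_bias` converts
    a fitted (coefficient, width) pair into degrees of peak bias.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    delta = np.asarray(delta, dtype=float)
    out = delta * np.exp(-(delta**2) / (2.0 * width**2))
    return out if out.ndim else float(out)


def peak_bias(coefficient: float, width: float) -> tuple[float, float]:
    """Peak of ``b·dog_basis(Δ, w)`` over Δ: (peak value in degrees, Δ at peak).

    Positive peaks mean attraction under the Δ = prior − current sign
    convention.  Closed form: value ``b·w·e^{−½}`` attained at Δ = w.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    return coefficient * width * np.exp(-0.5), width


def bic(rss: float, n_obs: int, n_params: int) -> float:
    """Gaussian-likelihood BIC up to a model-independent constant.

    ``n·ln(rss/n) + k·ln(n)``; the dropped constant ``n·(ln 2π + 1)`` is
    shared by all models fit to the same observations, so ΔBIC is exact.
    """
    if rss <= 0:
        raise ValueError("rss must be > 0 (perfect fits have no finite BIC)")
    if n_obs <= n_params:
        raise ValueError("need n_obs > n_params")
    return n_obs * np.log(rss / n_obs) + n_params * np.log(n_obs)


@dataclass
class FitResult:
    """A fitted family member: coefficients, chosen widths, fit statistics."""

    spec: ModelSpec
    widths: tuple[float, ...]
    params: dict[str, float]
    bse: dict[str, float]
    r_squared: float
    rss: float
    n_obs: int
    n_params: int
    bic: float

    def predict(self, delta, loc=None):
        """Fitted bias curve evaluated at Δ (and location dummy)."""
        delta = np.asarray(delta, dtype=float)
        y = np.full(delta.shape, self.params["intercept"])
        for i, w in enumerate(self.widths):
            y = y + self.params[f"delta{i + 1}"] * dog_basis(delta, w)
        if self.spec.location_interaction:
            loc = np.zeros_like(delta) if loc is None else np.asarray(loc, dtype=float)
            for i, w in enumerate(self.widths):
                y = y + self.params[f"delta{i + 1}:loc"] * dog_basis(delta, w) * loc
        return y

    def peaks(self) -> dict[str, dict[str, float]]:
        """Peak bias (degrees) and its Δ location for each component."""
        out = {}
        for i, w in enumerate(self.widths):
            term = f"delta{i + 1}"
            value, at = peak_bias(self.params[term], w)
            out[term] = {"peak_deg": value, "at_delta_deg": at, "width_deg": w}
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "widths": list(self.widths),
            "params": dict(self.params),
            "bse": dict(self.bse),
            "r_squared": self.r_squared,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "bic": self.bic,
            "peaks": self.peaks(),
        }


class _Gram:
    """Sufficient statistics for every candidate design in the family.

    One basis column per grid width; all candidate normal equations are
    assembled from the cross-products below, so the O(grid²) width search
    for the two-component models never touches the data again.
    """

    def __init__(self, delta, error, loc, widths):
        delta = np.asarray(delta, dtype=float)
        error = np.asarray(error, dtype=float)
        self.widths = np.asarray(widths, dtype=float)
        if self.widths.size == 0 or np.any(self.widths <= 0):
            raise ValueError("width grid must be nonempty and positive")
        B = delta[:, None] * np.exp(-(delta**2)[:, None] / (2.0 * self.widths**2)[None, :])
        self.n = delta.size
        self.sy = float(error.sum())
        self.syy = float(error @ error)
        self.sst = self.syy - self.sy**2 / self.n
        self.u = B.sum(axis=0)
        self.v = B.T @ error
        self.S = B.T @ B
        self.loc = None
        if loc is not None:
            L = np.asarray(loc).astype(bool)
            if L.any() and not L.all():
                BL = B[L]
                self.uL = BL.sum(axis=0)
                self.vL = BL.T @ error[L]
                self.SL = BL.T @ BL
                self.loc = L
        ii, jj = np.triu_indices(self.widths.size, k=1)
        sep = self.widths[jj] >= 2.0 * self.widths[ii]  # octave separation
        self._ii, self._jj = ii[sep], jj[sep]

    def _best(self, XtX, Xty):
        """Solve the batched normal equations; return (index, rss) of max r²."""
        try:
            beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
            rss = self.syy - np.einsum("...k,...k->...", beta, Xty)
        except np.linalg.LinAlgError:  # rare singular candidates: loop and skip
            rss = np.full(XtX.shape[0], np.inf)
            for k in range(XtX.shape[0]):
                try:
                    b = np.linalg.solve(XtX[k], Xty[k])
                    rss[k] = self.syy - b @ Xty[k]
                except np.linalg.LinAlgError:
                    continue
        k = int(np.argmin(rss))  # max r² == min rss; ties → first (smallest widths)
        return k, float(rss[k])

    def search(self, spec: ModelSpec):
        """Best width assignment for ``spec``: (widths tuple, rss)."""
        W = self.widths.size
        if spec.n_components == 0:
            return (), self.sst
        if spec.location_interaction and self.loc is None:
            raise ValueError(
                f"model {spec.name} needs a location dummy with both levels present"
            )
        n, u, v, S = self.n, self.u, self.v, self.S
        if spec.n_components == 1:
            if not spec.location_interaction:
                XtX = np.empty((W, 2, 2))
                XtX[:, 0, 0] = n
                XtX[:, 0, 1] = XtX[:, 1, 0] = u
                XtX[:, 1, 1] = np.diag(S)
                Xty = np.stack([np.full(W, self.sy), v], axis=1)
            else:
                XtX = np.empty((W, 3, 3))
                XtX[:, 0, 0] = n
                XtX[:, 0, 1] = XtX[:, 1, 0] = u
                XtX[:, 0, 2] = XtX[:, 2, 0] = self.uL
                XtX[:, 1, 1] = np.diag(S)
                XtX[:, 1, 2] = XtX[:, 2, 1] = np.diag(self.SL)
                XtX[:, 2, 2] = np.diag(self.SL)
                Xty = np.stack([np.full(W, self.sy), v, self.vL], axis=1)
            k, rss = self._best(XtX, Xty)
            return (float(self.widths[k]),), rss

        ii, jj = self._ii, self._jj  # pairs with w2 >= 2*w1 (see module docstring)
        P = ii.size
        if P == 0:
            raise ValueError("width grid admits no pair with w2 >= 2*w1")
        if not spec.location_interaction:
            XtX = np.empty((P, 3, 3))
            XtX[:, 0, 0] = n
            XtX[:, 0, 1] = XtX[:, 1, 0] = u[ii]
            XtX[:, 0, 2] = XtX[:, 2, 0] = u[jj]
            XtX[:, 1, 1] = S[ii, ii]
            XtX[:, 1, 2] = XtX[:, 2, 1] = S[ii, jj]
            XtX[:, 2, 2] = S[jj, jj]
            Xty = np.stack([np.full(P, self.sy), v[ii], v[jj]], axis=1)
        else:
            uL, vL, SL = self.uL, self.vL, self.SL
            XtX = np.empty((P, 5, 5))
            XtX[:, 0, 0] = n
            XtX[:, 0, 1] = XtX[:, 1, 0] = u[ii]
            XtX[:, 0, 2] = XtX[:, 2, 0] = u[jj]
            XtX[:, 0, 3] = XtX[:, 3, 0] = uL[ii]
            XtX[:, 0, 4] = XtX[:, 4, 0] = uL[jj]
            XtX[:, 1, 1] = S[ii, ii]
            XtX[:, 1, 2] = XtX[:, 2, 1] = S[ii, jj]
            XtX[:, 1, 3] = XtX[:, 3, 1] = SL[ii, ii]
            XtX[:, 1, 4] = XtX[:, 4, 1] = SL[ii, jj]
            XtX[:, 2, 2] = S[jj, jj]
            XtX[:, 2, 3] = XtX[:, 3, 2] = SL[ii, jj]
            XtX[:, 2, 4] = XtX[:, 4, 2] = SL[jj, jj]
            XtX[:, 3, 3] = SL[ii, ii]
            XtX[:, 3, 4] = XtX[:, 4, 3] = SL[ii, jj]
            XtX[:, 4, 4] = SL[jj, jj]
            Xty = np.stack([np.full(P, self.sy), v[ii], v[jj], vL[ii], vL[jj]], axis=1)
        k, rss = self._best(XtX, Xty)
        return (float(self.widths[ii[k]]), float(self.widths[jj[k]])), rss


def _design_matrix(delta, loc, spec: ModelSpec, widths):
    delta = np.asarray(delta, dtype=float)
    cols = [np.ones_like(delta)]
    for w in widths:
        cols.append(dog_basis(delta, w))
    if spec.location_interaction:
        L = np.asarray(loc, dtype=float)
        for w in widths:
            cols.append(dog_basis(delta, w) * L)
    return np.column_stack(cols)


def _refit(delta, error, loc, spec, widths, cluster_groups=None) -> FitResult:
    X = _design_matrix(delta, loc, spec, widths)
    error = np.asarray(error, dtype=float)
    if error.size <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    model = sm.OLS(error, X)
    if cluster_groups is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_groups)})
    else:
        res = model.fit()
    terms = spec.term_names()
    rss = float(res.ssr)
    r2 = 0.0 if spec.n_components == 0 else float(res.rsquared)
    if not np.isfinite(r2):  # zero-variance response: define r² = 0
        r2 = 0.0
    # a perfect fit (rss = 0) has no finite Gaussian BIC; keep the fit usable
    bic_value = bic(rss, error.size, X.shape[1]) if rss > 0 else float("-inf")
    return FitResult(
        spec=spec,
        widths=tuple(float(w) for w in widths),
        params=dict(zip(terms, map(float, res.params))),
        bse=dict(zip(terms, map(float, res.bse))),
        r_squared=r2,
        rss=rss,
        n_obs=int(error.size),
        n_params=X.shape[1],
        bic=bic_value,
    )


def fit_dog_model(
    delta,
    error,
    loc=None,
    spec: ModelSpec | str = "d1",
    width_grid=None,
    cluster_groups=None,
    fixed_widths=None,
) -> FitResult:
    """Fit one family member to pooled (Δ, error[, loc]) data.

    Searches every candidate width assignment on ``width_grid`` (two-
    component models search pairs w₂ ≥ 2·w₁ jointly), keeps the one with
    the highest r² (ties broken toward smaller w₁, then w₂), and refits
    it by OLS.  ``fixed_widths`` skips the search and fits the
    coefficients at the given widths — used when contrasting
    coefficients between data subsets, which requires both fits to share
    one basis.  ``cluster_groups`` switches on participant-clustered
    robust standard errors (off by default: the analysis pools across
    participants).
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    if fixed_widths is not None:
        widths = tuple(float(w) for w in np.atleast_1d(fixed_widths))
        if len(widths) != spec.n_components:
            raise ValueError(
                f"{spec.name} needs {spec.n_components} width(s), got {len(widths)}"
            )
        return _refit(delta, error, loc, spec, widths, cluster_groups)
    widths = DEFAULT_WIDTH_GRID if width_grid is None else np.asarray(width_grid, float)
    gram = _Gram(delta, error, loc, widths)
    best_widths, _ = gram.search(spec)
    return _refit(delta, error, loc, spec, best_widths, cluster_groups)


def fit_model_family(
    delta,
    error,
    loc=None,
    specs=None,
    width_grid=None,
) -> dict[str, FitResult]:
    """Fit several family members sharing one Gram-matrix precomputation."""
    if specs is None:
        specs = MODEL_FAMILY if loc is not None else MODEL_FAMILY[:3]
    specs = [ModelSpec.from_name(s) if isinstance(s, str) else s for s in specs]
    widths = DEFAULT_WIDTH_GRID if width_grid is None else np.asarray(width_grid, float)
    gram = _Gram(delta, error, loc, widths)
    out = {}
    for spec in specs:
        best_widths, _ = gram.search(spec)
        out[spec.name] = _refit(delta, error, loc, spec, best_widths)
    return out


def _evidence_label(delta_bic: float) -> str:
    if delta_bic == 0.0:
        return "worst"
    if delta_bic >= 6.0:
        return "strong"
    if delta_bic >= 2.0:
        return "positive"
    return "weak"


@dataclass
class ComparisonTable:
    """BIC/ΔBIC across the family; ΔBIC = 0 for the worst model, larger = better."""

    table: pd.DataFrame  # columns: model, bic, delta_bic, evidence
    best_model: str

    def to_dict(self) -> dict:
        return {"best_model": self.best_model, "models": self.table.to_dict("records")}


def compare_models(fits) -> ComparisonTable:
    """Rank ≥2 fits of the same observations by BIC.

    ΔBIC is computed relative to the *largest* BIC (worst model = 0,
    larger = better); evidence labels follow the 2 ("positive") and 6
    ("strong") thresholds.  The best model has the smallest BIC and the
    largest ΔBIC.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits were computed on different n_obs {sorted(n_obs)}; BIC not comparable")
    bics = np.array([f.bic for f in fits])
    delta = bics.max() - bics
    best = fits[int(np.argmin(bics))].spec.name
    table = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "bic": bics,
            "delta_bic": delta,
            "evidence": [_evidence_label(d) for d in delta],
        }
    )
    return ComparisonTable(table=table, best_model=best)


def compare_coefficients(fit_a: FitResult, fit_b: FitResult, term: str) -> tuple[float, float]:
    """Two-sample z-test between the same term of two independent fits.

    ``z = (b_a − b_b) / √(SE_a² + SE_b²)``; two-sided p from the standard
    normal.  Used to contrast Δ2 components between similarity halves.
    """
    for f in (fit_a, fit_b):
        if term not in f.params:
            raise KeyError(f"term {term!r} not in fitted model {f.spec.name}")
    se = np.hypot(fit_a.bse[term], fit_b.bse[term])
    z = (fit_a.params[term] - fit_b.params[term]) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def split_by_similarity(trials: pd.DataFrame, threshold: float = 45.0):
    """Partition distractor-present trials by |previous probe − distractor|.

    similar: |Δ| < threshold; dissimilar: |Δ| ≥ threshold.  Trials without
    a defined previous-probe/distractor difference are excluded from both.
    """
    if not (0.0 < threshold < 90.0):
        raise ValueError("threshold must be in (0, 90)")
    d = trials["prev_probe_distractor_delta"]
    eligible = trials["distractor_present"].astype(bool) & d.notna()
    similar = trials[eligible & (d.abs() < threshold)]
    dissimilar = trials[eligible & (d.abs() >= threshold)]
    for name, part in (("similar", similar), ("dissimilar", dissimilar)):
        if part.empty:
            warnings.warn(f"similarity split: {name} subset is empty")
    return similar, dissimilar


def smooth_curve(delta, errors, window: float = 21.0) -> pd.DataFrame:
    """Moving average (and SD) of errors in a sliding window over Δ.

    For each integer-degree centre in (−90, 90], returns the mean, SD and
    count of the errors whose Δ lies strictly within ±window/2 degrees of
    the centre — a window of total width ``window`` (so ``window=1``
    degenerates to per-degree bins), with distance taken on the
    180°-periodic circle; empty centres are omitted.  For plotting only —
    models are fit to unsmoothed data.
    """
    window = float(window)
    if window < 1 or window % 2 != 1:
        raise ValueError("window must be an odd width in degrees")
    delta = np.asarray(delta, dtype=float)
    errors = np.asarray(errors, dtype=float)
    half = window / 2.0
    rows = []
    for c in np.arange(-89.0, 91.0):
        dist = np.abs(np.mod(delta - c + 90.0, 180.0) - 90.0)
        sel = dist < half
        n = int(sel.sum())
        if n == 0:
            continue
        e = errors[sel]
        rows.append((c, float(e.mean()), float(e.std(ddof=1)) if n > 1 else 0.0, n))
    return pd.DataFrame(rows, columns=["delta", "mean", "sd", "n"])


def prepare_predictor(annotated: pd.DataFrame, predictor: str):
    """Extract (Δ, error, loc) arrays for one predictor from an annotated table.

    ``predictor`` is ``"prev_probe"`` (all trials with a previous trial in
    the session) or ``"distractor"`` (distractor-present trials).  ``loc``
    is the location dummy, random = 0, fixed = 1.
    """
    col = {"prev_probe": "delta_prev_probe", "distractor": "delta_distractor"}.get(predictor)
    if col is None:
        raise ValueError("predictor must be 'prev_probe' or 'distractor'")
    sub = annotated[annotated[col].notna()]
    delta = sub[col].to_numpy(dtype=float)
    error = sub["adjustment_error"].to_numpy(dtype=float)
    loc = (sub["location_condition"] == "fixed").to_numpy(dtype=int)
    return delta, error, loc
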