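"""Species-level carbon stock regression models.

Plot-level AGC/BGC (t·hm⁻²) are regressed on plot-mean feature variables.
The workflow mirrors standard small-sample biomass modelling practice:

1. Pearson screening ranks candidate predictors by |r| with the response.
2. A univariate ordinary-least-squares model is fit on the top-ranked
   predictor; only slopes significant at P < 0.05 are retained.
3. Multivariate models enumerate small predictor subsets of the
   top-ranked candidates, discard collinear subsets by variance
   inflation factor (VIF ≥ 10 flags, VIF ≥ 3 rejects) and insignificant
   coefficients, and rank survivors by leave-one-out cross-validated R².
4. Because some species predict better when pooled, every species
   combination (singletons plus all multi-species subsets) is fit, and a
   partition of the species set that maximizes mean LOOCV R² decides
   which species share a model.

With 10 plots per species this stays deliberately linear: tree-based or
nonparametric regressors overfit at this sample size.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionModel:
    """Linear carbon model routed to one or more species.

    ``coefficients[0]`` is the intercept, the rest align with
    ``predictors``.  LOOCV metrics use the predicted-residual (PRESS)
    form: R² = 1 − Σ(yᵢ−ŷ₍₋ᵢ₎)² / Σ(yᵢ−ȳ)².
    """

    response: str
    group: tuple[str, ...]
    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    p_values: tuple[float, ...] = ()
    fit_r2: float = float("nan")
    loocv_r2: float = float("nan")
    loocv_rmse: float = float("nan")
    max_vif: float = float("nan")
    n_plots: int = 0

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.predictors) + 1:
            raise ValueError("need one coefficient per predictor plus intercept")

    def predict(self, table) -> np.ndarray:
        """Evaluate the linear model on a table/dict of predictor columns."""
        out = np.full_like(
            np.asarray(table[self.predictors[0]], dtype=float), self.coefficients[0]
        ) if self.predictors else np.array([self.coefficients[0]])
        for name, beta in zip(self.predictors, self.coefficients[1:]):
            out = out + beta * np.asarray(table[name], dtype=float)
        return out

    @property
    def slope_p_max(self) -> float:
        return max(self.p_values[1:]) if len(self.p_values) > 1 else float("nan")

    def passes_significance(self, threshold: float = 0.05) -> bool:
        return len(self.p_values) > 1 and self.slope_p_max < threshold

    def to_dict(self) -> dict:
        return dict(
            response=self.response, group=list(self.group),
            predictors=list(self.predictors),
            coefficients=list(self.coefficients),
            p_values=list(self.p_values), fit_r2=self.fit_r2,
            loocv_r2=self.loocv_r2, loocv_rmse=self.loocv_rmse,
            max_vif=self.max_vif, n_plots=self.n_plots,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            response=d["response"], group=tuple(d["group"]),
            predictors=tuple(d["predictors"]),
            coefficients=tuple(d["coefficients"]),
            p_values=tuple(d.get("p_values", ())),
            fit_r2=d.get("fit_r2", float("nan")),
            loocv_r2=d.get("loocv_r2", float("nan")),
            loocv_rmse=d.get("loocv_rmse", float("nan")),
            max_vif=d.get("max_vif", float("nan")),
            n_plots=d.get("n_plots", 0),
        )


class ModelRegistry:
    """species → {response → RegressionModel}; shared-group models allowed."""

    def __init__(self, models: list[RegressionModel]):
        self.models = list(models)
        self._route: dict[tuple[str, str], RegressionModel] = {}
        for m in models:
            for sp in m.group:
                key = (sp, m.response)
                if key in self._route:
                    raise ValueError(f"species {sp!r} covered twice for {m.response}")
                self._route[key] = m

    def lookup(self, species: str, response: str) -> RegressionModel:
        try:
            return self._route[(species, response)]
        except KeyError:
            raise KeyError(
                f"no {response} model registered for species {species!r}"
            ) from None

    def species(self) -> list[str]:
        return sorted({s for s, _ in self._route})

    def predictors_needed(self) -> list[str]:
        names: set[str] = set()
        for m in self.models:
            names.update(m.predictors)
        return sorted(names)

    def to_json(self) -> str:
        return json.dumps([m.to_dict() for m in self.models], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelRegistry":
        return cls([RegressionModel.from_dict(d) for d in json.loads(text)])

    @classmethod
    def from_file(cls, path) -> "ModelRegistry":
        return cls.from_json(Path(path).read_text())

    def to_file(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def published_registry() -> ModelRegistry:
    """The best-performing field-published models shipped as defaults.

    AGC/BGC from H_Mean for the pooled *R. stylosa*–*A. marina* group,
    from RE_Mean for *A. corniculatum*, and from texture metrics for
    *B. gymnorrhiza*.
    """
    text = resources.files("mangrovecarbon.data").joinpath(
        "published_models.json"
    ).read_text()
    return ModelRegistry.from_json(text)


#: Plausible plot-mean feature ranges used when simulating from the
#: published models (predictor units as mapped by those models).
DEFAULT_FEATURE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "R_stylosa": {"H_Mean": (3.5, 6.0)},
    "A_marina": {"H_Mean": (1.5, 3.4)},
    "A_corniculatum": {"H_Mean": (1.2, 2.2), "RE_Mean": (23.5, 27.5)},
    "B_gymnorrhiza": {"H_Mean": (1.8, 3.2)},
    "_common": {
        "RE_Mean": (20.0, 29.0),
        "B_Var": (0.05, 0.40),
        "R_Con": (0.2, 2.0),
        "NIR_Hom": (0.3, 0.9),
        "B_Con": (0.1, 1.5),
        "NDVI": (0.5, 0.9),
    },
}


def simulate_plot_table(
    registry: ModelRegistry,
    n_per_species: int = 10,
    noise_frac: float = 0.075,
    seed: int = 0,
    feature_ranges: dict | None = None,
) -> pd.DataFrame:
    """Plot table whose carbon responses follow a registry's models exactly.

    Features are drawn uniformly from per-species ranges (species-specific
    entries override the ``_common`` ones); each response is the routed
    model's prediction plus Gaussian noise with SD = ``noise_frac`` times
    the response's deterministic range within the model's group.  Used as
    a parameter-recovery benchmark: refitting this table should recover
    the generating coefficients and grouping.
    """
    ranges = DEFAULT_FEATURE_RANGES if feature_ranges is None else feature_ranges
    rng = np.random.default_rng(seed)
    rows = []
    for sp in registry.species():
        span = dict(ranges.get("_common", {}))
        span.update(ranges.get(sp, {}))
        for i in range(n_per_species):
            row = {"plot_id": f"{sp}_{i + 1:02d}", "species": sp}
            for name, (lo, hi) in span.items():
                row[name] = rng.uniform(lo, hi)
            rows.append(row)
    table = pd.DataFrame(rows)
    for response in ("AGC", "BGC"):
        vals = np.zeros(len(table))
        for model in (m for m in registry.models if m.response == response):
            sel = table["species"].isin(model.group).to_numpy()
            pred = model.predict(table.loc[sel])
            spread = float(np.ptp(pred))
            vals[sel] = pred + rng.normal(0, noise_frac * spread, sel.sum())
        table[response] = vals
    return table


# --------------------------------------------------------------------------
# screening and fitting

def pearson_screen(
    plot_table: pd.DataFrame, response: str, predictors=None
) -> pd.DataFrame:
    """Pearson r (and two-tailed p) of every predictor against the response.

    Ranked by |r| descending; zero-variance predictors are skipped and
    flagged in the ``skipped`` column of the attrs.
    """
    if len(plot_table) < 3:
        raise ValueError("need at least 3 plots")
    if predictors is None:
        predictors = [
            c for c in plot_table.columns
            if c not in ("plot_id", "species", "pixel_count", "AGC", "BGC")
            and pd.api.types.is_numeric_dtype(plot_table[c])
        ]
    if response not in plot_table:
        raise ValueError(f"response {response!r} missing")
    y = plot_table[response].to_numpy(float)
    rows, skipped = [], []
    for name in predictors:
        x = plot_table[name].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            skipped.append(name)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(dict(variable=name, r=float(r), p=float(p)))
    if not rows:
        raise ValueError("all candidate predictors have zero variance")
    out = pd.DataFrame(rows)
    out = out.reindex(out.r.abs().sort_values(ascending=False, kind="stable").index)
    out = out.reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_univariate(
    plot_table: pd.DataFrame, predictor: str, response: str
) -> RegressionModel:
    """OLS of the response on a single predictor, with LOOCV metrics."""
    if len(plot_table) < 3:
        raise ValueError("need at least 3 plots")
    x = plot_table[predictor].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    y = plot_table[response].to_numpy(float)
    res = _ols(y, plot_table[[predictor]])
    try:
        r2, rmse = loocv(plot_table, [predictor], response)
    except ValueError:  # n = 3: too few plots for leave-one-out metrics
        r2, rmse = float("nan"), float("nan")
    return RegressionModel(
        response=response,
        group=tuple(sorted(plot_table["species"].unique()))
        if "species" in plot_table else (),
        predictors=(predictor,),
        coefficients=tuple(res.params),
        p_values=tuple(res.pvalues),
        fit_r2=float(res.rsquared),
        loocv_r2=r2, loocv_rmse=rmse,
        max_vif=1.0, n_plots=len(plot_table),
    )


def vif(design: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor per predictor: 1/(1−R²ⱼ of j on the rest).

    Perfect collinearity yields ``inf``.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than predictors")
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        res = _ols(X[:, j], pd.DataFrame(others))
        r2 = min(res.rsquared, 1.0)
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def loocv(
    plot_table: pd.DataFrame, predictors: list[str], response: str
) -> tuple[float, float]:
    """Leave-one-out prediction metrics for an OLS model.

    Each plot is predicted from a refit on the remaining n−1; RMSE over
    predicted residuals, R² in the PRESS form with the global mean (may
    be negative for uninformative predictors).
    """
    n = len(plot_table)
    p = len(predictors)
    if n < p + 3:
        raise ValueError(f"need ≥ {p + 3} plots for {p} predictors")
    y = plot_table[response].to_numpy(float)
    X = plot_table[list(predictors)].to_numpy(float)
    Xc = np.column_stack([np.ones(n), X])
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        A, b = Xc[keep], y[keep]
        if np.linalg.matrix_rank(A) < Xc.shape[1]:
            raise ValueError(f"singular refit when leaving out plot index {i}")
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        preds[i] = Xc[i] @ beta
    press = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - press / sst if sst > 0 else float("nan")
    return r2, float(np.sqrt(press / n))


def fit_multivariate(
    plot_table: pd.DataFrame,
    candidate_predictors: list[str],
    response: str,
    vif_detect: float = 10.0,
    vif_accept: float = 3.0,
    p_threshold: float = 0.05,
    max_terms: int = 3,
    top_k: int = 8,
) -> tuple[RegressionModel | None, pd.DataFrame]:
    """Best multivariate model over small subsets of top-correlated candidates.

    Subsets of size 2..max_terms from the ``top_k`` highest-|r| candidates
    are fit; subsets with max VIF ≥ ``vif_accept`` or any slope
    p ≥ ``p_threshold`` are rejected.  Survivors rank by LOOCV R².
    Returns (best model or None, per-subset report with rejection reasons).
    """
    n = len(plot_table)
    if n <= max_terms + 1:
        raise ValueError("too few plots for the requested model size")
    screen = pearson_screen(plot_table, response, candidate_predictors)
    ranked = screen.variable.tolist()[:top_k]
    report_rows = []
    candidates: list[RegressionModel] = []
    for size in range(2, max_terms + 1):
        for subset in itertools.combinations(ranked, size):
            row = dict(predictors="+".join(subset), n_terms=size)
            X = plot_table[list(subset)]
            try:
                vifs = vif(X)
            except ValueError as exc:
                row["status"] = f"vif failed: {exc}"
                report_rows.append(row)
                continue
            row["max_vif"] = float(np.max(vifs))
            if np.max(vifs) >= vif_accept:
                row["status"] = (
                    "collinear (VIF ≥ %g)" % vif_detect
                    if np.max(vifs) >= vif_detect
                    else "rejected (VIF ≥ %g)" % vif_accept
                )
                report_rows.append(row)
                continue
            y = plot_table[response].to_numpy(float)
            res = _ols(y, X)
            row["fit_r2"] = float(res.rsquared)
            if np.max(res.pvalues[1:]) >= p_threshold:
                row["status"] = "insignificant coefficient (p ≥ %g)" % p_threshold
                report_rows.append(row)
                continue
            r2, rmse = loocv(plot_table, list(subset), response)
            row.update(status="ok", loocv_r2=r2, loocv_rmse=rmse)
            report_rows.append(row)
            candidates.append(
                RegressionModel(
                    response=response,
                    group=tuple(sorted(plot_table["species"].unique()))
                    if "species" in plot_table else (),
                    predictors=subset,
                    coefficients=tuple(res.params),
                    p_values=tuple(res.pvalues),
                    fit_r2=float(res.rsquared),
                    loocv_r2=r2, loocv_rmse=rmse,
                    max_vif=float(np.max(vifs)), n_plots=n,
                )
            )
    report = pd.DataFrame(report_rows)
    if not candidates:
        return None, report
    best = max(candidates, key=lambda m: m.loocv_r2)
    return best, report


# --------------------------------------------------------------------------
# species-combination selection

def _set_partitions(items: list):
    """All partitions of a set (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def candidate_groups(species: list[str]) -> list[tuple[str, ...]]:
    """All singletons plus every multi-species subset (11 for 4 species)."""
    out = []
    for size in range(1, len(species) + 1):
        out.extend(itertools.combinations(species, size))
    return out


def select_models(
    plot_table: pd.DataFrame,
    responses: tuple[str, ...] = ("AGC", "BGC"),
    candidate_predictors: list[str] | None = None,
    p_threshold: float = 0.05,
    vif_detect: float = 10.0,
    vif_accept: float = 3.0,
    max_terms: int = 3,
    top_k: int = 8,
    min_plots: int = 5,
) -> tuple[ModelRegistry, pd.DataFrame]:
    """Fit every species combination and choose the best covering partition.

    ``plot_table`` holds one row per plot (feature columns + species +
    responses).  Per group and response the better of the univariate
    (top-|r| predictor) and multivariate models by LOOCV R² is the group
    candidate; the species partition maximizing mean LOOCV R² (ties →
    fewer groups, then lower summed LOOCV RMSE) forms the registry.
    """
    species = sorted(plot_table["species"].unique())
    if len(species) < 1:
        raise ValueError("no species in plot table")
    sizes = plot_table.groupby("species").size()
    small = sizes[sizes < min_plots]
    if len(small):
        raise ValueError(f"species with too few plots: {dict(small)}")

    best_by_group: dict[tuple[str, ...], dict[str, RegressionModel]] = {}
    report_rows = []
    for group in candidate_groups(species):
        sub = plot_table[plot_table["species"].isin(group)]
        for response in responses:
            entries: list[RegressionModel] = []
            screen = pearson_screen(sub, response, candidate_predictors)
            top_var = screen.variable.iloc[0]
            try:
                uni = fit_univariate(sub, top_var, response)
                if uni.passes_significance(p_threshold):
                    entries.append(uni)
                    status_uni = "ok"
                else:
                    status_uni = "insignificant"
            except ValueError as exc:
                status_uni = str(exc)
                uni = None
            multi, _rep = fit_multivariate(
                sub, candidate_predictors or screen.variable.tolist(), response,
                vif_detect=vif_detect, vif_accept=vif_accept,
                p_threshold=p_threshold, max_terms=max_terms, top_k=top_k,
            )
            if multi is not None:
                entries.append(multi)
            chosen = max(entries, key=lambda m: m.loocv_r2) if entries else None
            report_rows.append(
                dict(
                    group="+".join(group), response=response,
                    univariate_top=top_var, univariate_status=status_uni,
                    univariate_loocv_r2=uni.loocv_r2 if uni else np.nan,
                    multivariate_loocv_r2=multi.loocv_r2 if multi else np.nan,
                    chosen="none" if chosen is None else
                    ("univariate" if chosen is uni else "multivariate"),
                    loocv_r2=chosen.loocv_r2 if chosen else np.nan,
                    loocv_rmse=chosen.loocv_rmse if chosen else np.nan,
                )
            )
            if chosen is not None:
                best_by_group.setdefault(tuple(group), {})[response] = chosen
    report = pd.DataFrame(report_rows)

    selected: list[RegressionModel] = []
    for response in responses:
        best_score = None
        best_models = None
        for partition in _set_partitions(species):
            groups = [tuple(sorted(g)) for g in partition]
            models = []
            ok = True
            for g in groups:
                m = best_by_group.get(g, {}).get(response)
                if m is None:
                    ok = False
                    break
                models.append(m)
            if not ok:
                continue
            mean_r2 = float(np.mean([m.loocv_r2 for m in models]))
            score = (-mean_r2, len(groups), sum(m.loocv_rmse for m in models))
            if best_score is None or score < best_score:
                best_score = score
                best_models = models
        if best_models is None:
            raise ValueError(
                f"no valid covering partition for {response}; see report"
            )
        selected.extend(best_models)
    return ModelRegistry(selected), report
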