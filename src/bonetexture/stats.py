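"""Association of texture attributes with BMD and interobserver concordance.

Two model classes follow the familiar model/results idiom: construct from
data, call :meth:`fit`, read estimates off the returned results object.

* :class:`TextureAssociation` regresses bone mineral density (BMD, g/cm²)
  on each texture attribute — unadjusted (model 1) and adjusted for age and
  BMI (model 2) — and reports the attribute slope, its two-sided p-value
  and the marginal Pearson correlation.
* :class:`InterRaterAgreement` quantifies the agreement between two raters'
  feature tables with Lin's concordance correlation coefficient (CCC),
  its 95% confidence interval and a conventional strength label.

The underlying estimators (:func:`fit_model1`, :func:`fit_model2`,
:func:`lin_ccc`, :func:`strength_label`, :func:`compare_groups`) are exposed
as plain functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DegeneratePredictorError,
    JoinError,
    SchemaError,
    UndefinedConcordanceError,
)
from .glcm import ATTRIBUTE_NAMES

__all__ = [
    "AssociationResult",
    "ConcordanceResult",
    "fit_model1",
    "fit_model2",
    "lin_ccc",
    "strength_label",
    "compare_groups",
    "TextureAssociation",
    "TextureAssociationResults",
    "InterRaterAgreement",
    "InterRaterAgreementResults",
    "STRENGTH_LABELS",
]

#: Agreement-strength ranges: label applies to values in [lower, next lower).
#: Boundaries belong to the upper label (0.20 is "fair"); negatives are "poor".
STRENGTH_LABELS: tuple[tuple[float, str], ...] = (
    (0.80, "almost perfect"),
    (0.60, "substantial"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (-np.inf, "poor"),
)


@dataclass(frozen=True)
class AssociationResult:
    """One row of the attribute–BMD association table."""

    attribute: str
    estimated_coefficient: float
    p_value: float
    pearson_r: float
    model: str  # "model1" (simple) or "model2" (age/BMI adjusted)
    n: int


@dataclass(frozen=True)
class ConcordanceResult:
    """Lin's CCC with its confidence interval and strength label."""

    attribute: str
    ccc: float
    ci_low: float
    ci_high: float
    strength: str
    n: int


def _clean_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def fit_model1(feature, bmd, attribute: str = "") -> AssociationResult:
    """Simple linear regression of BMD on one texture attribute.

    Returns the OLS slope, its two-sided p-value (t distribution, n−2
    degrees of freedom) and the sample Pearson correlation.
    """
    x, y = _clean_pair(feature, bmd, 3)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(
            f"attribute {attribute or 'feature'} has zero variance"
        )
    res = scipy.stats.linregress(x, y)
    return AssociationResult(
        attribute=attribute,
        estimated_coefficient=float(res.slope),
        p_value=float(res.pvalue),
        pearson_r=float(res.rvalue),
        model="model1",
        n=int(x.size),
    )


def fit_model2(feature, bmd, age, bmi, attribute: str = "") -> AssociationResult:
    """Age- and BMI-adjusted linear regression of BMD on one attribute.

    Covariates with zero variance are dropped (they are absorbed by the
    intercept, and the fit then reduces to the simple regression); a design
    that remains rank deficient raises :class:`CollinearityError`.
    pearson_r reports the marginal (unadjusted) correlation alongside the
    adjusted slope.
    """
    x, y = _clean_pair(feature, bmd, 5)
    covariates = []
    for name, values in (("age", age), ("bmi", bmi)):
        v = np.asarray(values, dtype=float).ravel()
        if v.size != x.size:
            raise ValueError(f"{name} length {v.size} does not match n={x.size}")
        if np.ptp(v) > 0:
            covariates.append(v)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(
            f"attribute {attribute or 'feature'} has zero variance"
        )
    design = np.column_stack([np.ones_like(x), x, *covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            f"design matrix for attribute {attribute or 'feature'} is rank deficient"
        )
    fit = sm.OLS(y, design).fit()
    r = float(np.corrcoef(x, y)[0, 1])
    return AssociationResult(
        attribute=attribute,
        estimated_coefficient=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        pearson_r=r,
        model="model2",
        n=int(x.size),
    )


def strength_label(value: float) -> str:
    """Conventional agreement-strength label for a concordance value.

    Ranges: poor < 0.20 ≤ fair < 0.40 ≤ moderate < 0.60 ≤ substantial
    < 0.80 ≤ almost perfect ≤ 1.00; negative values are poor.
    """
    if value > 1.0 + 1e-12:
        raise ValueError(f"agreement coefficient must be <= 1, got {value}")
    for lower, label in STRENGTH_LABELS:
        if value >= lower:
            return label
    return "poor"  # pragma: no cover


def lin_ccc(x, y, alpha: float = 0.05, attribute: str = "") -> ConcordanceResult:
    """Lin's concordance correlation coefficient with asymptotic CI.

    Uses the original 1/n (biased) moment estimator
    ``ccc = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)``.  The confidence interval
    applies the inverse-hyperbolic-tangent (Fisher z) transform with Lin's
    asymptotic variance and back-transforms the bounds.
    """
    x, y = _clean_pair(x, y, 3)
    n = x.size
    mx, my = float(x.mean()), float(y.mean())
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    if sx2 == 0.0 or sy2 == 0.0:
        raise UndefinedConcordanceError(
            f"concordance undefined for constant sequence(s)"
            + (f" in attribute {attribute}" if attribute else "")
        )
    denom = sx2 + sy2 + (mx - my) ** 2
    ccc = 2.0 * sxy / denom
    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location-shift relative to the scale

    if 1.0 - ccc**2 < 1e-12:
        lo = hi = ccc
    else:
        # variance of atanh(ccc), written via c = ccc / r so it stays finite
        # as r -> 0
        c = 2.0 * np.sqrt(sx2 * sy2) / denom
        one_m = 1.0 - ccc**2
        var_z = (
            (1.0 - r**2) * c**2 / one_m
            + 2.0 * ccc**2 * c * (1.0 - ccc) * u**2 / one_m**2
            - ccc**2 * c**2 * u**4 / (2.0 * one_m**2)
        ) / (n - 2)
        var_z = max(var_z, 0.0)
        z = np.arctanh(ccc)
        zcrit = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
        half = zcrit * np.sqrt(var_z)
        lo = float(np.tanh(z - half))
        hi = float(np.tanh(z + half))
    return ConcordanceResult(
        attribute=attribute,
        ccc=float(ccc),
        ci_low=lo,
        ci_high=hi,
        strength=strength_label(float(ccc)),
        n=int(n),
    )


def compare_groups(values, group) -> float:
    """One-way ANOVA p-value across the groups defined by ``group`` labels.

    With two groups this equals the pooled-variance two-sided t-test
    (F = t²).  If every value is identical across groups the statistic is
    0 and p = 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    group = np.asarray(group).ravel()
    if values.size != group.size:
        raise ValueError("values and group labels must have equal length")
    labels = pd.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[group == g] for g in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if values.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(values) == 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = scipy.stats.f_oneway(*samples)
    if np.isnan(p):  # zero within-group variance with distinct means
        return 0.0
    return float(p)


def _feature_frame(features: pd.DataFrame, attributes) -> pd.DataFrame:
    frame = features.copy()
    if "id" in frame.columns:
        frame = frame.set_index("id")
    missing = [a for a in attributes if a not in frame.columns]
    if missing:
        raise SchemaError(f"feature table is missing attribute column(s) {missing}")
    return frame


class TextureAssociation:
    """Per-attribute association of BMD with texture, models 1 and 2.

    Parameters
    ----------
    features : DataFrame
        One row per subject with an ``id`` column (or index) and one column
        per texture attribute.
    cohort : DataFrame
        Covariate table with columns ``id, age, bmi, bmd``.
    attributes : sequence of str, optional
        Attribute columns to analyse; defaults to the canonical 22.
    """

    def __init__(self, features: pd.DataFrame, cohort: pd.DataFrame, attributes=None):
        self.attributes = tuple(attributes) if attributes is not None else ATTRIBUTE_NAMES
        feats = _feature_frame(features, self.attributes)
        coh = cohort.copy()
        if "id" in coh.columns:
            coh = coh.set_index("id")
        only_feats = sorted(set(feats.index) - set(coh.index))
        only_coh = sorted(set(coh.index) - set(feats.index))
        if only_feats or only_coh:
            raise JoinError(
                f"feature/cohort ids do not match 1:1 "
                f"(only in features: {only_feats}; only in cohort: {only_coh})"
            )
        coh = coh.loc[feats.index]
        self.data = feats.join(coh[["age", "bmi", "bmd"]])
        self.nobs = len(self.data)

    def fit(self, alpha: float = 0.05) -> "TextureAssociationResults":
        model1, model2 = [], []
        for name in self.attributes:
            x = self.data[name].to_numpy()
            y = self.data["bmd"].to_numpy()
            model1.append(fit_model1(x, y, attribute=name))
            model2.append(
                fit_model2(
                    x,
                    y,
                    self.data["age"].to_numpy(),
                    self.data["bmi"].to_numpy(),
                    attribute=name,
                )
            )
        return TextureAssociationResults(model1, model2, alpha=alpha)


class TextureAssociationResults:
    """Fitted per-attribute associations; rows in canonical attribute order."""

    def __init__(self, model1, model2, alpha: float = 0.05):
        self.model1 = list(model1)
        self.model2 = list(model2)
        self.alpha = float(alpha)

    def to_frame(self, benjamini_hochberg: bool = False) -> pd.DataFrame:
        """Association report: model-1 slope/p/r plus the adjusted slope/p.

        ``significant`` flags raw model-1 p < alpha, matching the study
        design of reporting unadjusted significance over the 22 attributes.
        A Benjamini–Hochberg-adjusted column can be added on request and is
        off by default.
        """
        frame = pd.DataFrame(
            {
                "attribute": [r.attribute for r in self.model1],
                "estimated_coefficient": [r.estimated_coefficient for r in self.model1],
                "p_value": [r.p_value for r in self.model1],
                "pearson_r": [r.pearson_r for r in self.model1],
                "model2_coefficient": [r.estimated_coefficient for r in self.model2],
                "model2_p_value": [r.p_value for r in self.model2],
            }
        )
        frame["significant"] = frame["p_value"] < self.alpha
        if benjamini_hochberg:
            frame["p_value_bh"] = sm.stats.multipletests(
                frame["p_value"].to_numpy(), method="fdr_bh"
            )[1]
        return frame

    def significant(self) -> list[str]:
        return [r.attribute for r in self.model1 if r.p_value < self.alpha]

    def summary(self) -> str:
        frame = self.to_frame()
        header = (
            f"BMD ~ texture attribute associations "
            f"(n={self.model1[0].n}, alpha={self.alpha})"
        )
        return header + "\n" + frame.to_string(index=False, float_format="%.5g")


class InterRaterAgreement:
    """Lin concordance between two raters' feature tables, per attribute."""

    def __init__(self, features_a: pd.DataFrame, features_b: pd.DataFrame, attributes=None):
        self.attributes = tuple(attributes) if attributes is not None else ATTRIBUTE_NAMES
        a = _feature_frame(features_a, self.attributes)
        b = _feature_frame(features_b, self.attributes)
        if set(a.index) != set(b.index):
            raise JoinError("the two feature tables must cover the same subject ids")
        self.a = a
        self.b = b.loc[a.index]
        self.nobs = len(a)

    def fit(self, alpha: float = 0.05) -> "InterRaterAgreementResults":
        results = [
            lin_ccc(
                self.a[name].to_numpy(),
                self.b[name].to_numpy(),
                alpha=alpha,
                attribute=name,
            )
            for name in self.attributes
        ]
        return InterRaterAgreementResults(results, alpha=alpha)


class InterRaterAgreementResults:
    """Per-attribute concordance results with CI and strength labels."""

    def __init__(self, results, alpha: float = 0.05):
        self.results = list(results)
        self.alpha = float(alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "attribute": [r.attribute for r in self.results],
                "ccc": [r.ccc for r in self.results],
                "ci_low": [r.ci_low for r in self.results],
                "ci_high": [r.ci_high for r in self.results],
                "strength": [r.strength for r in self.results],
            }
        )

    def summary(self) -> str:
        header = (
            f"Interobserver concordance (Lin CCC, n={self.results[0].n}, "
            f"{100 * (1 - self.alpha):.0f}% CI)"
        )
        return header + "\n" + self.to_frame().to_string(index=False, float_format="%.5g")
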