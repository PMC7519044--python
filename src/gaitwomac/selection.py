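"""Key-feature selection: ANOVA screen, pairwise t-tests, subscale analysis.

The procedure mirrors a strict two-gate screen across the three severity
classes:

1. a classical one-way fixed-effects ANOVA per feature at alpha = 0.0001;
2. for features passing the screen, pooled-variance Student's t-tests for
   the three class pairs (mild-moderate, moderate-severe, mild-severe) at
   the Bonferroni-corrected alpha = 0.00003;
3. features significant in *all three* comparisons are the key features,
   ordered by ascending ANOVA p-value.

The same two gates are then repeated with classes defined by each WOMAC
subscale to map which key features associate with pain, stiffness and
physical function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

ALPHA_ANOVA = 0.0001
#: Bonferroni level as printed (0.0001 / 3 rounded); set
#: ``alpha_pairwise=0.0001 / 3`` for the exact-division variant.
ALPHA_PAIRWISE = 0.00003

PAIRS = (("mild", "moderate"), ("moderate", "severe"), ("mild", "severe"))
_PAIR_COLUMNS = {
    ("mild", "moderate"): "p_mild_moderate",
    ("moderate", "severe"): "p_moderate_severe",
    ("mild", "severe"): "p_mild_severe",
}


@dataclass
class SelectionResult:
    """Per-feature test results and flags; ``table`` columns: F, p_anova,
    passed_anova, p_mild_moderate, p_moderate_severe, p_mild_severe,
    passed_all_pairs, key_feature."""

    table: pd.DataFrame
    alpha_anova: float
    alpha_pairwise: float
    subscale_features: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def key_features(self) -> List[str]:
        return select_key_features(self)


def _class_arrays(
    X: pd.DataFrame, classes: Sequence[str], min_per_class: int = 2
) -> Dict[str, np.ndarray]:
    labels = np.asarray(classes)
    if labels.shape[0] != X.shape[0]:
        raise ValidationError("class labels must align with feature-matrix rows")
    present = [g for g in ("mild", "moderate", "severe") if (labels == g).any()]
    if len(present) != 3:
        raise ValidationError(f"need all three severity classes, found {present}")
    out = {}
    for g in present:
        Xg = X.values[labels == g]
        if Xg.shape[0] < min_per_class:
            raise ValidationError(f"class {g!r} has fewer than {min_per_class} subjects")
        out[g] = Xg
    return out


def anova_screen(
    X: pd.DataFrame, classes: Sequence[str], alpha: float = ALPHA_ANOVA
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature column.

    Returns a frame indexed by feature id with columns F, p_anova,
    passed_anova (p < alpha).
    """
    groups = _class_arrays(X, classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups.values(), axis=0)
    out = pd.DataFrame({"F": F, "p_anova": p}, index=X.columns)
    out["passed_anova"] = out["p_anova"] < alpha
    out.loc[~np.isfinite(out["p_anova"]), "passed_anova"] = False
    return out


def pairwise_ttests(
    X: pd.DataFrame,
    classes: Sequence[str],
    alpha: float = ALPHA_PAIRWISE,
    restrict_to: Optional[Sequence[str]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample Student's t-tests (pooled variance, two-sided) per class
    pair, computed only for ``restrict_to`` features (default: all).

    A pair with zero pooled variance yields an undefined p (NaN) and fails
    the gate.  ``welch=True`` switches to the unequal-variance variant.
    """
    groups = _class_arrays(X, classes)
    cols = list(X.columns if restrict_to is None else restrict_to)
    col_idx = [X.columns.get_loc(c) for c in cols]
    out = pd.DataFrame(index=pd.Index(cols, name=X.columns.name))
    passed = np.ones(len(cols), dtype=bool)
    for pair in PAIRS:
        a = groups[pair[0]][:, col_idx]
        b = groups[pair[1]][:, col_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
        out[_PAIR_COLUMNS[pair]] = p
        passed &= np.nan_to_num(p, nan=1.0) < alpha
    out["passed_all_pairs"] = passed
    return out


def run_selection(
    X: pd.DataFrame,
    classes: Sequence[str],
    alpha_anova: float = ALPHA_ANOVA,
    alpha_pairwise: float = ALPHA_PAIRWISE,
    welch: bool = False,
) -> SelectionResult:
    """Apply both gates and assemble the full selection table."""
    nan_cols = X.columns[X.isna().any(axis=0)]
    if len(nan_cols):
        logger.warning("excluding %d feature(s) with missing values before testing", len(nan_cols))
        X = X.drop(columns=nan_cols)
    table = anova_screen(X, classes, alpha_anova)
    screened = list(table.index[table["passed_anova"]])
    tt = pairwise_ttests(X, classes, alpha_pairwise, restrict_to=screened, welch=welch)
    table = table.join(tt, how="left")
    table["passed_all_pairs"] = (
        table["passed_all_pairs"].astype("boolean").fillna(False).astype(bool)
    )
    table["key_feature"] = table["passed_anova"] & table["passed_all_pairs"]
    return SelectionResult(table=table, alpha_anova=alpha_anova, alpha_pairwise=alpha_pairwise)


def select_key_features(selection: SelectionResult) -> List[str]:
    """Key features ordered by ascending ANOVA p (ties broken by id)."""
    t = selection.table
    keys = t[t["key_feature"]]
    order = keys.sort_values(["p_anova"], kind="stable")
    return sorted(order.index, key=lambda fid: (t.loc[fid, "p_anova"], fid))


def subscale_association(
    X: pd.DataFrame,
    subscale_classes: Dict[str, Sequence[str]],
    key_features: Sequence[str],
    alpha_anova: float = ALPHA_ANOVA,
    alpha_pairwise: float = ALPHA_PAIRWISE,
) -> Dict[str, List[str]]:
    """Repeat the two-gate screen on the key features with classes defined
    by each subscale; returns the per-subscale significant feature sets.

    A subscale whose classes cannot support the tests (a class with < 2
    subjects or a missing class) is flagged unevaluable (empty list,
    logged) and the others proceed.
    """
    Xk = X[list(key_features)]
    out: Dict[str, List[str]] = {}
    for subscale, classes in subscale_classes.items():
        try:
            res = run_selection(Xk, classes, alpha_anova, alpha_pairwise)
        except ValidationError as exc:
            logger.warning("subscale %s unevaluable: %s", subscale, exc)
            out[subscale] = []
            continue
        out[subscale] = res.key_features
    return out
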