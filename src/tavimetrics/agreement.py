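"""Agreement statistics for paired measurement tables.

Compares two raters (e.g. an automated pipeline and an expert, or two
experts) measurement-by-measurement: mean absolute relative error with its
confidence interval, Pearson correlation with a Fisher-z confidence
interval, and Bland–Altman limits of agreement.

The confidence-interval half-width is Z·s/√(n−1).  The √(n−1) denominator
is the printed convention this package reproduces by default; the standard
√n form is available via ``ci_denominator="n"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ci_eq1",
    "mean_abs_rel_error",
    "pearson_ci",
    "bland_altman",
    "AgreementResult",
    "compare_tables",
    "bland_altman_plot",
]


def ci_eq1(mean: float, sd: float, n: int, z: float = 1.96,
           ci_denominator: str = "n-1") -> tuple[float, float]:
    """Confidence interval x̃ ± Z·s/√(n−1).

    ``ci_denominator="n"`` switches to the standard-error form Z·s/√n.
    """
    if n < 2:
        raise ValidationError("need n >= 2 for a confidence interval")
    if sd < 0:
        raise ValidationError("standard deviation must be >= 0")
    if ci_denominator == "n-1":
        denom = np.sqrt(n - 1)
    elif ci_denominator == "n":
        denom = np.sqrt(n)
    else:
        raise ValidationError("ci_denominator must be 'n-1' or 'n'")
    hw = z * sd / denom
    return float(mean - hw), float(mean + hw)


def _aligned(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    if len(a) < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {len(a)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("vectors contain non-finite values")
    return a, b


def mean_abs_rel_error(a, b, z: float = 1.96, ci_denominator: str = "n-1"
                       ) -> dict:
    """Mean absolute relative error of ``a`` against reference ``b``, in %.

    Per case e = |a−b| / |b| · 100; the reference (denominator) is the
    second argument — conventionally the expert.  Cases with a zero
    reference are excluded (counted in ``n_excluded``).  The CI is
    :func:`ci_eq1` over the per-case errors.
    """
    a, b = _aligned(a, b, min_n=2)
    nonzero = b != 0
    n_excluded = int(np.sum(~nonzero))
    a, b = a[nonzero], b[nonzero]
    if len(a) < 2:
        raise ValidationError("fewer than 2 pairs with nonzero reference")
    e = np.abs(a - b) / np.abs(b) * 100.0
    mean = float(np.mean(e))
    sd = float(np.std(e, ddof=1))
    lo, hi = ci_eq1(mean, sd, len(e), z, ci_denominator)
    return {"mean_pct": mean, "ci": (lo, hi), "n": len(e),
            "n_excluded": n_excluded, "per_case_pct": e}


def pearson_ci(a, b, z: float = 1.96) -> dict:
    """Sample Pearson r with a Fisher-z confidence interval.

    The interval uses the Fisher transform z_r = atanh(r) with standard
    error 1/√(n−3) — the field-standard method, recorded in the output
    metadata since different CI constructions exist.
    """
    a, b = _aligned(a, b, min_n=4)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("correlation undefined: zero variance")
    r = float(stats.pearsonr(a, b).statistic)
    n = len(a)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        zr = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(zr - z * se), np.tanh(zr + z * se)
    return {"r": r, "ci": (float(lo), float(hi)), "n": n,
            "ci_method": "fisher-z"}


def bland_altman(a, b, z: float = 1.96) -> dict:
    """Bland–Altman agreement: mean difference and limits of agreement.

    d = a − b; limits are mean(d) ± 1.96·sd(d) with the sample sd (n−1
    denominator).  Also returns the (pair mean, difference) points for
    plotting.  Swapping the raters negates the mean difference and mirrors
    the limits.
    """
    a, b = _aligned(a, b, min_n=3)
    d = a - b
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - z * sd,
        "loa_high": mean_diff + z * sd,
        "sd": sd,
        "means": (a + b) / 2.0,
        "diffs": d,
        "n": len(a),
    }


@dataclass
class AgreementResult:
    """Per-measurement agreement summary between two raters."""

    measurement: str
    n: int
    mean_abs_rel_error_pct: float
    mare_ci: tuple[float, float]
    mean_signed_diff: float          # several published tables report this
    pearson_r: float
    pearson_ci: tuple[float, float]
    ba_mean_diff: float
    ba_loa: tuple[float, float]
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "measurement": self.measurement,
            "n": self.n,
            "mean_abs_rel_error_pct": self.mean_abs_rel_error_pct,
            "mare_ci_low": self.mare_ci[0],
            "mare_ci_high": self.mare_ci[1],
            "mean_signed_diff": self.mean_signed_diff,
            "pearson_r": self.pearson_r,
            "pearson_ci_low": self.pearson_ci[0],
            "pearson_ci_high": self.pearson_ci[1],
            "ba_mean_diff": self.ba_mean_diff,
            "ba_loa_low": self.ba_loa[0],
            "ba_loa_high": self.ba_loa[1],
        }


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   case_column: str = "case_id",
                   z: float = 1.96,
                   ci_denominator: str = "n-1") -> list[AgreementResult]:
    """Full agreement analysis over two paired measurement tables.

    Each table has a case-identifier column plus one column per
    measurement; rows are aligned by case id, which must match exactly
    (same set, no duplicates).  Rater A is the first table, the reference
    rater B the second.
    """
    for name, t in (("A", table_a), ("B", table_b)):
        if case_column not in t.columns:
            raise ValidationError(f"table {name} lacks column {case_column!r}")
        if t[case_column].duplicated().any():
            raise ValidationError(f"table {name} has duplicate case ids")
    ids_a = set(table_a[case_column])
    ids_b = set(table_b[case_column])
    if ids_a != ids_b:
        raise ValidationError(
            f"case ids differ between tables: {sorted(ids_a ^ ids_b)[:5]} ...")
    a = table_a.set_index(case_column).sort_index()
    b = table_b.set_index(case_column).sort_index()
    common = [c for c in a.columns if c in b.columns]
    if not common:
        raise ValidationError("tables share no measurement columns")

    results = []
    for col in common:
        va, vb = a[col].to_numpy(float), b[col].to_numpy(float)
        mare = mean_abs_rel_error(va, vb, z, ci_denominator)
        pr = pearson_ci(va, vb, z)
        ba = bland_altman(va, vb, z)
        results.append(AgreementResult(
            measurement=col,
            n=len(va),
            mean_abs_rel_error_pct=mare["mean_pct"],
            mare_ci=mare["ci"],
            mean_signed_diff=float(np.mean(va - vb)),
            pearson_r=pr["r"],
            pearson_ci=pr["ci"],
            ba_mean_diff=ba["mean_diff"],
            ba_loa=(ba["loa_low"], ba["loa_high"]),
            extras={"mare_n_excluded": mare["n_excluded"]},
        ))
    return results


def bland_altman_plot(a, b, ax=None, label_a: str = "A", label_b: str = "B"):
    """Scatter of per-case differences against pair means, with the bias
    line and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    ba = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["means"], ba["diffs"], s=12, alpha=0.7)
    ax.axhline(ba["mean_diff"], color="k", lw=1, label="mean difference")
    for y in (ba["loa_low"], ba["loa_high"]):
        ax.axhline(y, color="gray", lw=1, ls="--")
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    ax.legend(loc="best", fontsize=8)
    return ax
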