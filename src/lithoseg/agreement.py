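"""Method-agreement statistics: ICC, Bland-Altman, Bartlett.

Sign convention throughout: differences are reference - estimate.

The intraclass correlation is ICC(A,1) — two-way random effects, absolute
agreement, single measurement — treating {estimate, reference} as two
raters.  Absolute agreement is the conservative choice for a
method-versus-reference comparison because it penalizes systematic bias as
well as scatter; the consistency variant ICC(C,1) is available via
``variant``.

Variance homogeneity across the four segmentation methods is assessed with
the classical Bartlett chi-square test applied separately to the volume
differences and the diameter differences, yielding one p-value per
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    UndefinedICCError,
)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of one method with the reference for one quantity."""

    n: int
    icc: float
    mean_diff: float
    std_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float = float("nan")


@dataclass(frozen=True)
class VarianceComparison:
    """Bartlett homogeneity-of-variances test across k methods."""

    k: int
    statistic: float
    dof: int
    p_value: float


def icc(estimates, references, variant: str = "A1") -> float:
    """Intraclass correlation between paired estimate and reference vectors.

    Computed from the two-way ANOVA mean squares with n subjects and k = 2
    raters:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(references, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("estimates and references must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("ICC needs at least 3 paired observations")
    data = np.stack([x, y], axis=1)  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise UndefinedICCError("no variance in either measurement set")
    if variant.upper() == "A1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant.upper() == "C1":
        denom = msr + (k - 1) * mse
    else:
        raise InsufficientDataError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        raise UndefinedICCError("degenerate ICC denominator")
    return float((msr - mse) / denom)


def bland_altman(estimates, references) -> tuple[AgreementReport, np.ndarray]:
    """Agreement report plus (mean-of-pair, difference) points for plotting.

    Differences are reference - estimate; limits of agreement are
    mean ± 1.96 SD with the n-1 denominator.
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(references, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 paired observations")
    diffs = y - x
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    try:
        icc_val = icc(x, y)
    except (UndefinedICCError, InsufficientDataError):
        icc_val = float("nan")
    if x.std() > 0 and y.std() > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = float("nan")
    report = AgreementReport(
        n=len(x),
        icc=icc_val,
        mean_diff=mean,
        std_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        pearson_r=r,
    )
    points = np.stack([(x + y) / 2, diffs], axis=1)
    return report, points


def bartlett_test(*difference_sets) -> VarianceComparison:
    """Classical Bartlett test of equal variances across k groups.

    Groups are per-method difference vectors (reference - estimate);
    volume and diameter are tested separately at the call site.
    """
    groups = [np.asarray(g, dtype=float) for g in difference_sets]
    if len(groups) < 2:
        raise InsufficientDataError("Bartlett needs at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InsufficientDataError("each Bartlett group needs n >= 2")
        if g.var(ddof=1) == 0:
            raise DegenerateVarianceError("a group has zero variance")
    stat, p = stats.bartlett(*groups)
    return VarianceComparison(k=len(groups), statistic=float(stat), dof=len(groups) - 1, p_value=float(p))


def evaluate_all_methods(
    estimates_by_method: dict,
    references,
) -> tuple[dict, dict]:
    """Agreement reports per (method, quantity) and Bartlett comparisons per quantity.

    ``estimates_by_method`` maps a method label to a list of StoneMeasurement;
    ``references`` is a list of RaterRecord-like objects.  Returns
    ``(reports, comparisons)`` where ``reports[(label, "volume")]`` is an
    AgreementReport and ``comparisons["volume"]`` a VarianceComparison
    across all methods (likewise for "diameter").
    """
    ref = {r.stone_id: (r.reference_volume_ml, r.reference_diameter_mm) for r in references}
    reports: dict = {}
    diffs: dict[str, dict] = {"volume": {}, "diameter": {}}
    for label, measurements in estimates_by_method.items():
        ids = [m.stone_id for m in measurements]
        vr = np.array([ref[i][0] for i in ids])
        dr = np.array([ref[i][1] for i in ids])
        ev = np.array([m.volume_ml for m in measurements])
        ed = np.array([m.diameter_mm for m in measurements])
        reports[(label, "volume")], _ = bland_altman(ev, vr)
        reports[(label, "diameter")], _ = bland_altman(ed, dr)
        diffs["volume"][label] = vr - ev
        diffs["diameter"][label] = dr - ed
    comparisons = {
        qty: bartlett_test(*[diffs[qty][label] for label in estimates_by_method])
        for qty in ("volume", "diameter")
    }
    return reports, comparisons


def plot_agreement(estimates, references, quantity_label: str, ax_pair=None):
    """Correlation and Bland-Altman panels for one method/quantity (cosmetic)."""
    import matplotlib.pyplot as plt

    x = np.asarray(estimates, dtype=float)
    y = np.asarray(references, dtype=float)
    report, points = bland_altman(x, y)
    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
    ax_corr, ax_ba = ax_pair
    ax_corr.scatter(y, x, s=12)
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax_corr.plot(lims, lims, "k--", lw=0.8)
    ax_corr.set_xlabel(f"reference {quantity_label}")
    ax_corr.set_ylabel(f"estimated {quantity_label}")
    ax_ba.scatter(points[:, 0], points[:, 1], s=12)
    for y0 in (report.mean_diff, report.loa_low, report.loa_high):
        ax_ba.axhline(y0, ls="--", lw=0.8, color="k")
    ax_ba.set_xlabel(f"mean {quantity_label}")
    ax_ba.set_ylabel("reference - estimate")
    return report, ax_pair
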