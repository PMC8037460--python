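"""Clinical endpoint computations and the study's statistical workflow.

Morphometry: endothelial cell density ECD (cells/mm^2), mean cell area
AVE (um^2), polymegathism index CV = 100 * SD(area)/AVE, pleomorphism
index 6A (percent hexagonal cells).  Statistics follow the study design:
a normality screen (Shapiro-Wilk plus a Kolmogorov-Smirnov test with
Lilliefors correction) routes each endpoint to parametric tests (t-test,
repeated-measures ANOVA) or non-parametric ones (rank-sum, Friedman),
with significance at alpha = 0.05 and no multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class StatsInputError(ValueError):
    pass


# ----------------------------------------------------------------------
# morphometry
# ----------------------------------------------------------------------

def percent_cell_loss(pre_mean: float, loss_mean: float,
                      ndigits: int | None = 1) -> float:
    """Percent endothelial cell loss, 100 * loss / preoperative density.

    Scale invariant; reported to one decimal by default
    (``ndigits=None`` returns the raw quotient).
    """
    if not pre_mean > 0:
        raise StatsInputError("pre_mean must be strictly positive")
    pct = 100.0 * loss_mean / pre_mean
    return pct if ndigits is None else round(pct, ndigits)


@dataclass(frozen=True)
class MorphometrySummary:
    ecd: float        # cells/mm^2, from 1e6 / AVE
    ave: float        # um^2
    cv: float         # percent, 100 * SD/AVE
    hex_pct: float    # percent hexagonal (6-apex) cells
    min_area: float
    max_area: float
    n_cells: int


def morphometry_summary(cell_areas, shapes) -> MorphometrySummary:
    """Summarize a field of endothelial cells.

    ``cell_areas`` in um^2; ``shapes`` are apex counts per cell (6 marks a
    hexagonal cell).  The SD in CV is the sample SD (ddof=1).
    """
    areas = np.asarray(cell_areas, float)
    shp = np.asarray(shapes)
    if areas.size == 0 or shp.size == 0:
        raise StatsInputError("empty morphometry input")
    if areas.size != shp.size:
        raise StatsInputError("cell_areas and shapes length mismatch")
    ave = float(areas.mean())
    sd = float(areas.std(ddof=1)) if areas.size > 1 else 0.0
    return MorphometrySummary(
        ecd=1e6 / ave, ave=ave, cv=100.0 * sd / ave,
        hex_pct=100.0 * float(np.mean(shp == 6)),
        min_area=float(areas.min()), max_area=float(areas.max()),
        n_cells=int(areas.size))


# ----------------------------------------------------------------------
# normality screen and tests
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    outcome: str            # "parametric" | "nonparametric"
    shapiro_p: float
    ks_p: float

    @property
    def parametric(self) -> bool:
        return self.outcome == "parametric"


def normality_screen(sample, alpha: float = ALPHA) -> ScreenResult:
    """Shapiro-Wilk + Lilliefors KS; parametric iff both give p > alpha."""
    x = np.asarray(sample, float)
    if x.size < 3:
        raise StatsInputError("normality screen needs n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant sample: normality undefined, routing to "
                      "nonparametric", stacklevel=2)
        return ScreenResult("nonparametric", 0.0, 0.0)
    from statsmodels.stats.diagnostic import lilliefors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw_p = float(stats.shapiro(x).pvalue)
        ks_p = float(lilliefors(x, dist="norm")[1])
    outcome = "parametric" if (sw_p > alpha and ks_p > alpha) \
        else "nonparametric"
    return ScreenResult(outcome, sw_p, ks_p)


@dataclass(frozen=True)
class TestResult:
    endpoint: str
    test: str
    statistic: float
    pvalue: float
    screen: str = ""

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA

    def __post_init__(self):
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value outside [0, 1]")


def compare_groups(a, b, endpoint: str = "", welch: bool = True,
                   study_routing: bool = False) -> TestResult:
    """Two-group comparison with normality-based routing.

    Both samples pass the screen -> two-sided t-test (Welch by default,
    classical Student's with ``welch=False``); otherwise a rank-based
    test.  ``study_routing=True`` reproduces the study's use of the
    Friedman test for non-parametric two-group comparisons (requires
    equal group sizes; it treats the two groups as repeated measures and
    degenerates to a sign-type test).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.array_equal(a, b):
        return TestResult(endpoint, "t" if welch else "t-student",
                          0.0, 1.0, "identical")
    sa, sb = normality_screen(a), normality_screen(b)
    if sa.parametric and sb.parametric:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return TestResult(endpoint, "t" if welch else "t-student",
                          float(res.statistic), float(res.pvalue),
                          "parametric")
    if study_routing and len(a) == len(b) and len(a) >= 3:
        res = _friedman_two(a, b)
        return TestResult(endpoint, "Friedman", *res, "nonparametric")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(endpoint, "rank-sum", float(res.statistic),
                      float(res.pvalue), "nonparametric")


def _friedman_two(a, b):
    # Friedman with k=2 treatments: chi2 from within-pair ranks
    ranks = np.where(a < b, 1.0, 2.0)
    tie = a == b
    ranks = np.where(tie, 1.5, ranks)
    r1 = ranks.sum()
    r2 = 3.0 * len(a) - r1   # ranks sum to 3 per pair
    n = len(a)
    chi2 = 12.0 / (n * 2 * 3) * (r1**2 + r2**2) - 3 * n * 3
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def longitudinal_course(cohort: pd.DataFrame, endpoint: str,
                        timepoints, group: str | None = None) -> TestResult:
    """Within-group progression of an endpoint over >= 3 timepoints.

    Columns ``{endpoint}_{tp}`` are screened; if every timepoint passes,
    a one-way repeated-measures ANOVA is used, otherwise the Friedman
    test.
    """
    if len(timepoints) < 3:
        raise StatsInputError("longitudinal course needs >= 3 timepoints")
    df = cohort if group is None else cohort[cohort["group"] == group]
    cols = []
    for tp in timepoints:
        col = f"{endpoint}_{tp}"
        if col not in df.columns:
            raise StatsInputError(f"missing column {col!r}")
        cols.append(df[col].to_numpy(float))
    if any(len(c) != len(cols[0]) for c in cols):
        raise StatsInputError("unequal column lengths in paired design")
    screens = [normality_screen(c) for c in cols]
    if all(s.parametric for s in screens):
        from statsmodels.stats.anova import AnovaRM
        n = len(cols[0])
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), len(cols)),
            "time": np.repeat(np.arange(len(cols)), n),
            "value": np.concatenate(cols),
        })
        tab = AnovaRM(long, "value", "subject", within=["time"]).fit()
        f = float(tab.anova_table["F Value"].iloc[0])
        p = float(tab.anova_table["Pr > F"].iloc[0])
        return TestResult(f"{endpoint} course", "ANOVA-RM", f, p,
                          "parametric")
    stat, p = stats.friedmanchisquare(*cols)
    return TestResult(f"{endpoint} course", "Friedman", float(stat),
                      float(p), "nonparametric")


def iop_peak_count(cohort: pd.DataFrame, threshold: float = 20.0,
                   timepoint: str = "6h",
                   by_group: bool = False):
    """Patients with IOP strictly above ``threshold`` at a timepoint."""
    col = f"iop_{timepoint}"
    if col not in cohort.columns:
        raise StatsInputError(f"missing column {col!r}")
    above = cohort[col] > threshold
    if by_group:
        return above.groupby(cohort["group"]).sum().astype(int).to_dict()
    return int(above.sum())
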