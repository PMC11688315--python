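"""The statistical battery: chi-square on pooled 2x2 counts, nested and
mixed (repeated-measures) ANOVA on per-animal summaries, and a Spearman
screen of baseline vs contagion activity.

Conventions
-----------
* The 2x2 chi-square is the uncorrected Pearson statistic by default; the
  Yates continuity correction is available but off, because pooled cohort
  comparisons in this paradigm are conventionally reported uncorrected.
* ANOVA F statistics are formed from the standard mean squares.  The
  denominator degrees of freedom can be *reported* in either of two
  conventions: ``"residual"`` — the textbook error df of the design — or
  ``"reported"`` (default) — the number of subjects minus one, the
  convention used in the behavioral-contagion literature this tool targets.
  p-values are always computed from the df pair actually reported, so the
  F -> p mapping is internally consistent under either convention.
* p-values are two-sided; no multiple-testing correction is applied (none
  is conventional for this battery), but report assembly counts the number
  of tests run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import ValidationError

DF_CONVENTIONS = ("reported", "residual")


@dataclass(frozen=True)
class TestResult:
    design_label: str
    effect: str
    statistic: float
    df1: int
    df2: int | None
    p_value: float

    def as_dict(self) -> dict:
        return asdict(self)


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input (e.g. a zero
    marginal in a contingency table, or a constant vector)."""


def chi_square_2x2(
    table, continuity_correction: bool = False, design_label: str = "chi-square 2x2"
) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table.

    ``table`` is ``[[a, b], [c, d]]`` with rows = cohorts and columns =
    outcome / non-outcome.  The statistic is ``N (ad - bc)^2 / (r1 r2 c1 c2)``
    with df = 1; with ``continuity_correction`` the Yates-corrected form is
    used instead.  A zero column marginal leaves the statistic undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("cells must be non-negative integers")
    (a, b), (c, d) = t
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = t.sum()
    if r1 < 1 or r2 < 1:
        raise UndefinedStatisticError("each cohort (row) needs at least one count")
    if c1 == 0 or c2 == 0:
        raise UndefinedStatisticError("zero column marginal: statistic undefined")
    dev = abs(a * d - b * c)
    if continuity_correction:
        dev = max(dev - n / 2.0, 0.0)
    stat = n * dev * dev / (r1 * r2 * c1 * c2)
    return TestResult(
        design_label=design_label,
        effect="independence",
        statistic=float(stat),
        df1=1,
        df2=None,
        p_value=float(sps.chi2.sf(stat, 1)),
    )


def _check_convention(df_convention: str) -> None:
    if df_convention not in DF_CONVENTIONS:
        raise ValueError(f"df_convention must be one of {DF_CONVENTIONS}")


def nested_anova(
    data: pd.DataFrame,
    value: str = "value",
    strain: str = "strain",
    cage: str = "cage",
    error_term: str = "residual",
    df_convention: str = "reported",
    design_label: str = "nested ANOVA",
) -> list[TestResult]:
    """Nested ANOVA: strain, with cage nested within strain.

    One row per animal.  Sums of squares follow the hierarchical
    decomposition

    .. math::

        SS_{strain} = \\sum_s n_s (\\bar y_s - \\bar y)^2, \\qquad
        SS_{cage(strain)} = \\sum_c n_c (\\bar y_c - \\bar y_{s(c)})^2,

    with the residual within cages.  ``error_term`` selects the denominator
    mean square for the strain test: ``"residual"`` (default) or ``"cage"``
    (test strain against the cage-within-strain mean square).  The
    cage(strain) effect is always tested against the residual.
    """
    _check_convention(df_convention)
    if error_term not in ("residual", "cage"):
        raise ValueError("error_term must be 'residual' or 'cage'")
    d = data[[value, strain, cage]].dropna()
    if d[value].isna().any():
        raise ValidationError("missing outcome values")
    sizes = d.groupby(cage).size()
    if (sizes < 2).any():
        bad = sorted(sizes[sizes < 2].index.astype(str))
        raise ValidationError(f"cages with a single animal have no within-cage variance: {bad}")
    n_strains = d[strain].nunique()
    if n_strains < 2:
        raise ValidationError("nested ANOVA needs at least two strains")
    if d.groupby(strain)[cage].nunique().min() < 2:
        raise ValidationError("nested ANOVA needs at least two cages per strain")
    # a cage must not span strains
    if (d.groupby(cage)[strain].nunique() > 1).any():
        raise ValidationError("a cage spans more than one strain")

    y = d[value].to_numpy(dtype=float)
    n_total = len(d)
    grand = y.mean()
    strain_means = d.groupby(strain)[value].transform("mean").to_numpy()
    cage_means = d.groupby(cage)[value].transform("mean").to_numpy()

    ss_strain = float(np.sum((strain_means - grand) ** 2))
    ss_cage = float(np.sum((cage_means - strain_means) ** 2))
    ss_res = float(np.sum((y - cage_means) ** 2))

    n_cages = d[cage].nunique()
    df_strain = n_strains - 1
    df_cage = n_cages - n_strains
    df_res = n_total - n_cages
    if df_res < 1:
        raise ValidationError("no residual degrees of freedom")

    ms_strain = ss_strain / df_strain
    ms_cage = ss_cage / df_cage
    ms_res = ss_res / df_res

    if error_term == "cage":
        f_strain = ms_strain / ms_cage if ms_cage > 0 else np.inf
        df2_strain_model = df_cage
    else:
        f_strain = ms_strain / ms_res if ms_res > 0 else np.inf
        df2_strain_model = df_res
    f_cage = ms_cage / ms_res if ms_res > 0 else np.inf

    if df_convention == "reported":
        df2_strain = df2_cage = n_total - 1
    else:
        df2_strain, df2_cage = df2_strain_model, df_res

    def res(effect, f, df1, df2):
        return TestResult(
            design_label=design_label,
            effect=effect,
            statistic=float(f),
            df1=int(df1),
            df2=int(df2),
            p_value=float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0,
        )

    return [
        res("strain", f_strain, df_strain, df2_strain),
        res("cage(strain)", f_cage, df_cage, df2_cage),
    ]


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "animal",
    between: str = "cage",
    df_convention: str = "reported",
    design_label: str = "RM ANOVA",
) -> list[TestResult]:
    """Mixed repeated-measures ANOVA: one within factor (two or more
    conditions per subject) and one between-subjects factor.

    Backed by :func:`pingouin.mixed_anova`.  Every subject must carry every
    within condition — a missing condition is an error, never imputed.
    Returns results for the within factor, the between factor, and their
    interaction.
    """
    import pingouin as pg  # deferred: pingouin import is slow

    _check_convention(df_convention)
    d = data[[dv, within, subject, between]].copy()
    if d[dv].isna().any():
        raise ValidationError("missing outcome values")
    conditions = sorted(d[within].unique())
    counts = d.groupby(subject)[within].nunique()
    if (counts != len(conditions)).any():
        bad = sorted(counts[counts != len(conditions)].index.astype(str))
        raise ValidationError(f"subjects missing a within condition: {bad}")
    if d[between].nunique() < 2:
        raise ValidationError("the between-subjects factor needs >= 2 levels")
    # the between factor must be constant within subject
    if (d.groupby(subject)[between].nunique() > 1).any():
        raise ValidationError("a subject appears under two between-factor levels")

    import warnings as _warnings

    with _warnings.catch_warnings():
        # a zero error mean square produces harmless 0/0 warnings; the
        # degenerate cases are resolved explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.mixed_anova(
            data=d, dv=dv, within=within, subject=subject, between=between,
            correction=False,
        )
    n_subjects = d[subject].nunique()
    effect_names = {0: "between", 1: "within", 2: "interaction"}

    out: list[TestResult] = []
    for i, row in aov.iterrows():
        f = float(row["F"])
        if not np.isfinite(f):
            # degenerate designs: a zero effect SS is "no effect" (F = 0);
            # a positive effect SS over a zero error SS is unbounded evidence
            f = 0.0 if float(row["SS"]) <= 1e-12 else np.inf
        df1 = int(row["DF1"])
        df2 = int(row["DF2"]) if df_convention == "residual" else n_subjects - 1
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        out.append(
            TestResult(
                design_label=design_label,
                effect=effect_names.get(i, str(row["Source"])),
                statistic=f,
                df1=df1,
                df2=df2,
                p_value=p,
            )
        )
    return out


def spearman_screen(
    baseline: pd.DataFrame,
    contagion: pd.DataFrame,
    parameters: list[str] | None = None,
    design_label: str = "Spearman screen",
) -> pd.DataFrame:
    """Spearman rank correlations of baseline vs contagion activity.

    Each parameter is correlated across animals between the two summaries.
    Animals with zero activity are included — zeros are valid ranks.  A
    constant vector leaves rho undefined; such rows carry ``NaN`` and a
    note instead of a fabricated value.

    Returns a tidy DataFrame: ``parameter, rho, p_value, n, note``.
    """
    from .windows import SUMMARY_VALUE_COLUMNS

    if parameters is None:
        parameters = list(SUMMARY_VALUE_COLUMNS)
    b = baseline.set_index("animal")
    c = contagion.set_index("animal")
    if set(b.index) != set(c.index):
        raise ValidationError("baseline and contagion summaries must cover the same animals")
    c = c.loc[b.index]
    rows = []
    for p in parameters:
        x = b[p].to_numpy(dtype=float)
        y = c[p].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append((p, np.nan, np.nan, len(x), "constant vector: rho undefined"))
            continue
        rho, pv = sps.spearmanr(x, y)
        rows.append((p, float(rho), float(pv), len(x), ""))
    return pd.DataFrame(rows, columns=["parameter", "rho", "p_value", "n", "note"])


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Tidy export: design_label, effect, statistic, df1, df2, p."""
    return pd.DataFrame([r.as_dict() for r in results])
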