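"""The confirmatory and post-hoc inner-crowd analysis pipeline.

Participants answer eight percentage-scale world-knowledge questions twice.
Accuracy is each participant's mean squared error (MSE) against the true
answers; the crowd-within claim is that the per-question average of the two
guesses has a lower MSE than either guess alone.  The pipeline cleans a
cohort (incomplete sessions, browser defocusing, answer look-ups, impossible
or blank answers), scores MSEs, runs the paired within-condition tests and
the unpaired between-condition test of the averaging benefit, attaches effect
sizes, confidence intervals and JZS Bayes factors, and issues two replication
verdicts per condition:

* traditional - both single-guess-vs-average t statistics positive with
  two-tailed p < alpha;
* detectability - additionally, neither effect-size estimate is
  significantly below d_33%, the effect the original study could detect with
  33% power at its own sample size (one-sided z-test on the normal SE
  sqrt(1/n + d^2/(2n))).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import effects
from .bayes import BayesFactorResult, jzs_bf01_one_sample, jzs_bf01_two_sample
from .effects import (
    EffectSizeEstimate,
    TestResult,
    dz_from_t,
    d_independent_from_summary,
    effect_ci,
    independent_summary_from_data,
    independent_t,
    paired_t,
)
from .power import PowerSpec, detectable_effect

__all__ = [
    "AnalysisConfig",
    "AccuracyTable",
    "CleaningRules",
    "ComparisonResult",
    "ConditionReport",
    "BetweenConditionResult",
    "ExclusionLog",
    "ParticipantRecord",
    "QuestionSet",
    "ReplicationReport",
    "accuracy_table",
    "analyze_study",
    "between_condition_test",
    "clean_cohort",
    "evaluate_replication",
    "within_condition_tests",
]

SCHEMA_VERSION = "1.0"

#: True answers used in the replication (percentages, updated world statistics).
CURRENT_STUDY_ANSWERS = (6.3, 43.3, 32.3, 13.4, 53.6, 54.8, 26.4, 22.4)
#: True answers as used in the original experiment.
ORIGINAL_STUDY_ANSWERS = (6.3, 44.4, 30.3, 10.5, 58.0, 72.4, 18.9, 20.3)

#: Original-study per-condition sample sizes used for the d_33% benchmark.
DEFAULT_ORIGINAL_N = {"immediate": 255, "delayed": 173}

CONDITIONS = ("immediate", "delayed")


@dataclass(frozen=True)
class QuestionSet:
    """An ordered set of questions with true percentage answers."""

    question_id: tuple[str, ...]
    truth: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.question_id) != len(self.truth):
            raise ValueError("question_id and truth must have equal length")
        if len(set(self.question_id)) != len(self.question_id):
            raise ValueError("question ids must be unique")
        if any(not 0.0 <= t <= 100.0 for t in self.truth):
            raise ValueError("all true answers must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.question_id)

    @property
    def truth_array(self) -> np.ndarray:
        return np.asarray(self.truth, dtype=float)

    @classmethod
    def default(cls) -> "QuestionSet":
        """The eight questions with the replication study's updated answers."""
        return cls(tuple(f"q{i}" for i in range(1, 9)), CURRENT_STUDY_ANSWERS)

    @classmethod
    def original(cls) -> "QuestionSet":
        """The same eight questions with the original study's answers."""
        return cls(tuple(f"q{i}" for i in range(1, 9)), ORIGINAL_STUDY_ANSWERS)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: condition, cleaning flags, and two guess vectors.

    Guesses are percentages on [0, 100]; NaN marks a blank answer.
    Out-of-range values are retained at load time and removed by the
    question-level cleaning rule.
    """

    participant_id: str
    condition: str
    guess1: np.ndarray
    guess2: np.ndarray
    completed: bool = True
    looked_up: bool = False
    defocused: bool = False
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        g1 = np.asarray(self.guess1, dtype=float)
        g2 = np.asarray(self.guess2, dtype=float)
        if g1.shape != g2.shape or g1.ndim != 1:
            raise ValueError("guess1 and guess2 must be 1-D and equal length")
        object.__setattr__(self, "guess1", g1)
        object.__setattr__(self, "guess2", g2)


@dataclass(frozen=True)
class CleaningRules:
    """Which exclusion rules to apply, in the fixed precedence
    incomplete -> defocused -> looked-up -> question-level."""

    require_complete: bool = True
    exclude_defocused: bool = True
    exclude_looked_up: bool = True
    drop_invalid_questions: bool = True


@dataclass
class ExclusionLog:
    """Cleaning accounting: which participants fell to which rule.

    ``question_level`` maps a retained participant to the question ids whose
    guesses were removed for being blank or outside [0, 100].
    """

    n_input: int
    incomplete: list[str] = field(default_factory=list)
    defocused: list[str] = field(default_factory=list)
    looked_up: list[str] = field(default_factory=list)
    question_level: dict[str, list[str]] = field(default_factory=dict)
    scoring_warnings: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.incomplete) + len(self.defocused) + len(self.looked_up)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "incomplete": len(self.incomplete),
            "defocused": len(self.defocused),
            "looked_up": len(self.looked_up),
            "question_level": sum(len(v) for v in self.question_level.values()),
            "retained": self.n_retained,
        }


def _valid_guess(g: np.ndarray) -> np.ndarray:
    return np.isfinite(g) & (g >= 0.0) & (g <= 100.0)


def clean_cohort(
    records: Sequence[ParticipantRecord],
    rules: CleaningRules = CleaningRules(),
    qs: QuestionSet | None = None,
) -> tuple[list[ParticipantRecord], ExclusionLog]:
    """Apply the pre-registered cleaning rules to a cohort.

    Participant-level rules fire in the order incomplete -> defocused ->
    looked-up; each excluded participant is counted once, under the first rule
    that matches.  The question-level rule then blanks BOTH guesses of any
    question with a blank or impossible (outside [0, 100]) answer in either
    guess.  Cleaning never fails; it only excludes, and is idempotent.
    """
    if qs is not None:
        for r in records:
            if r.guess1.size != len(qs):
                raise ValueError(
                    f"participant {r.participant_id!r} has {r.guess1.size} guesses for {len(qs)} questions"
                )
    log = ExclusionLog(n_input=len(records))
    retained: list[ParticipantRecord] = []
    for r in records:
        if rules.require_complete and not r.completed:
            log.incomplete.append(r.participant_id)
        elif rules.exclude_defocused and r.defocused:
            log.defocused.append(r.participant_id)
        elif rules.exclude_looked_up and r.looked_up:
            log.looked_up.append(r.participant_id)
        else:
            retained.append(r)
    if rules.drop_invalid_questions:
        cleaned = []
        for r in retained:
            bad = ~(_valid_guess(r.guess1) & _valid_guess(r.guess2))
            if bad.any():
                ids = qs.question_id if qs is not None else tuple(f"q{i + 1}" for i in range(r.guess1.size))
                log.question_level[r.participant_id] = [ids[i] for i in np.nonzero(bad)[0]]
                g1 = r.guess1.copy()
                g2 = r.guess2.copy()
                g1[bad] = np.nan
                g2[bad] = np.nan
                r = replace(r, guess1=g1, guess2=g2)
            cleaned.append(r)
        retained = cleaned
    return retained, log


#: Per-participant accuracy table: one row per participant with the MSE of
#: guess 1, guess 2 and the per-question average of both guesses, all computed
#: over that participant's retained questions (columns: participant_id,
#: condition, n_questions, mse_g1, mse_g2, mse_avg).
AccuracyTable = pd.DataFrame


def accuracy_table(
    records: Sequence[ParticipantRecord],
    qs: QuestionSet | None = None,
    log: ExclusionLog | None = None,
) -> AccuracyTable:
    """Score a cleaned cohort: per-participant MSEs of guess 1, guess 2 and their average.

    The average-guess MSE averages the guesses per question first and scores
    second (average-then-score), which by convexity can only improve on the
    mean of the two single-guess MSEs.  A question contributes only when both
    guesses are present; participants with no retained question are dropped
    with a warning.
    """
    qs = qs or QuestionSet.default()
    truth = qs.truth_array
    rows = []
    for r in records:
        if r.guess1.size != len(qs):
            raise ValueError(
                f"participant {r.participant_id!r} has {r.guess1.size} guesses for {len(qs)} questions"
            )
        keep = np.isfinite(r.guess1) & np.isfinite(r.guess2)
        if not keep.any():
            msg = f"participant {r.participant_id!r} has no retained questions; dropped from scoring"
            warnings.warn(msg, stacklevel=2)
            if log is not None:
                log.scoring_warnings.append(msg)
            continue
        e1 = r.guess1[keep] - truth[keep]
        e2 = r.guess2[keep] - truth[keep]
        e_avg = (r.guess1[keep] + r.guess2[keep]) / 2.0 - truth[keep]
        rows.append(
            {
                "participant_id": r.participant_id,
                "condition": r.condition,
                "n_questions": int(keep.sum()),
                "mse_g1": float(np.mean(e1**2)),
                "mse_g2": float(np.mean(e2**2)),
                "mse_avg": float(np.mean(e_avg**2)),
            }
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "n_questions", "mse_g1", "mse_g2", "mse_avg"]
    )


@dataclass(frozen=True)
class ComparisonResult:
    """One comparison: t-test, standardized effect with CI, and Bayes factor."""

    label: str
    test: TestResult
    effect: EffectSizeEstimate
    bayes: BayesFactorResult | None = None


@dataclass(frozen=True)
class ConditionReport:
    """Within-condition results: the three paired comparisons plus verdict slots."""

    condition: str
    n: int
    avg_vs_g1: ComparisonResult
    avg_vs_g2: ComparisonResult
    g1_vs_g2: ComparisonResult
    mse_summary: dict[str, float]
    traditional_success: bool | None = None
    detectability_success: bool | None = None
    d33: float | None = None


@dataclass(frozen=True)
class BetweenConditionResult:
    """Delayed-vs-immediate comparison of the averaging benefit for one reference guess."""

    reference: Literal["guess1", "guess2"]
    test: TestResult
    effect: EffectSizeEstimate
    bayes: BayesFactorResult | None = None
    mean_benefit: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ReplicationReport:
    """Everything one analysis run produces: per-condition tests, between-condition
    tests, replication verdicts and the cleaning log."""

    conditions: dict[str, ConditionReport]
    between: dict[str, BetweenConditionResult]
    alpha: float
    ci_level: float
    bf_scale: float | None
    exclusions: ExclusionLog | None = None
    schema_version: str = SCHEMA_VERSION


def _paired_comparison(
    label: str,
    single: np.ndarray,
    other: np.ndarray,
    ci_level: float,
    bf_scale: float | None,
) -> ComparisonResult:
    test = paired_t(single, other)
    est = EffectSizeEstimate(value=dz_from_t(test.t, test.df + 1), design="paired", n=test.df + 1)
    est = effect_ci(est, level=ci_level)
    bf = jzs_bf01_one_sample(test.t, test.df + 1, bf_scale) if bf_scale is not None else None
    return ComparisonResult(label=label, test=test, effect=est, bayes=bf)


def within_condition_tests(
    acc: AccuracyTable, ci_level: float = 0.95, bf_scale: float | None = 1.0
) -> ConditionReport:
    """The three paired t-tests of one condition, with effects, CIs and Bayes factors.

    Sign convention: t > 0 means the single guess has the larger MSE, i.e.
    averaging helps; the guess-1-vs-guess-2 test is positive when guess 1 is
    the less accurate of the two.
    """
    if len(acc) < 2:
        raise effects.InvalidSampleSizeError("within-condition tests need at least 2 participants")
    conditions = acc["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(f"accuracy table mixes conditions {sorted(conditions)}; pass one condition at a time")
    g1 = acc["mse_g1"].to_numpy()
    g2 = acc["mse_g2"].to_numpy()
    avg = acc["mse_avg"].to_numpy()
    avg_vs_g1 = _paired_comparison("avg_vs_g1", g1, avg, ci_level, bf_scale)
    avg_vs_g2 = _paired_comparison("avg_vs_g2", g2, avg, ci_level, bf_scale)
    g1_vs_g2 = _paired_comparison("g1_vs_g2", g1, g2, ci_level, bf_scale)
    summary = {
        "mean_mse_g1": float(g1.mean()),
        "sd_mse_g1": float(g1.std(ddof=1)),
        "mean_mse_g2": float(g2.mean()),
        "sd_mse_g2": float(g2.std(ddof=1)),
        "mean_mse_avg": float(avg.mean()),
        "sd_mse_avg": float(avg.std(ddof=1)),
        "r_g1_avg": float(np.corrcoef(g1, avg)[0, 1]),
        "r_g2_avg": float(np.corrcoef(g2, avg)[0, 1]),
    }
    return ConditionReport(
        condition=str(conditions[0]),
        n=len(acc),
        avg_vs_g1=avg_vs_g1,
        avg_vs_g2=avg_vs_g2,
        g1_vs_g2=g1_vs_g2,
        mse_summary=summary,
    )


def between_condition_test(
    acc_immediate: AccuracyTable,
    acc_delayed: AccuracyTable,
    reference: Literal["guess1", "guess2"] = "guess1",
    ci_level: float = 0.95,
    bf_scale: float | None = 1.0,
) -> BetweenConditionResult:
    """Unpaired test of the averaging benefit, delayed vs. immediate.

    The per-participant benefit is MSE(reference guess) - MSE(average guess);
    positive values mean averaging helped.  A pooled-variance Student t
    (df = n1 + n2 - 2) compares delayed against immediate benefits, so t > 0
    when the delay increased the benefit.
    """
    if len(acc_immediate) == 0 or len(acc_delayed) == 0:
        raise ValueError("both accuracy tables must be nonempty")
    col = {"guess1": "mse_g1", "guess2": "mse_g2"}[reference]
    ben_imm = (acc_immediate[col] - acc_immediate["mse_avg"]).to_numpy()
    ben_del = (acc_delayed[col] - acc_delayed["mse_avg"]).to_numpy()
    summ = independent_summary_from_data(ben_del, ben_imm)
    test = independent_t(summ)
    est = effect_ci(d_independent_from_summary(summ), level=ci_level)
    bf = jzs_bf01_two_sample(test.t, summ.n_1, summ.n_2, bf_scale) if bf_scale is not None else None
    return BetweenConditionResult(
        reference=reference,
        test=test,
        effect=est,
        bayes=bf,
        mean_benefit={"delayed": summ.mean_1, "immediate": summ.mean_2},
    )


def evaluate_replication(
    report: ConditionReport,
    original_n: int | None,
    alpha: float = 0.05,
) -> ConditionReport:
    """Attach the traditional and detectability verdicts to a condition report.

    Traditional success requires both single-vs-average tests to be positive
    and significant at ``alpha`` (two-tailed).  Detectability additionally
    requires that neither effect-size estimate is significantly below d_33%
    (one-sided z-test at ``alpha`` with SE = sqrt(1/n + d^2/(2n))), where
    d_33% comes from the original study's sample size; without that size the
    detectability verdict is unavailable (None).
    """
    from scipy import stats as _st

    tests = (report.avg_vs_g1, report.avg_vs_g2)
    traditional = all(c.test.t > 0 and c.test.p_two_tailed < alpha for c in tests)
    if original_n is None:
        return replace(report, traditional_success=traditional, detectability_success=None, d33=None)
    d33 = detectable_effect(original_n, PowerSpec(alpha=alpha, target_power=0.33))
    z_crit = _st.norm.ppf(alpha)
    not_below = True
    for c in tests:
        d, n = c.effect.value, c.effect.n
        se = np.sqrt(1.0 / n + d**2 / (2.0 * n))
        if (d - d33) / se < z_crit:  # significantly below d_33%
            not_below = False
    return replace(
        report,
        traditional_success=traditional,
        detectability_success=bool(traditional and not_below),
        d33=d33,
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of a full analysis run."""

    alpha: float = 0.05
    ci_level: float = 0.95
    bf_scale: float | None = 1.0
    cleaning: CleaningRules = CleaningRules()
    original_n: Mapping[str, int | None] = field(
        default_factory=lambda: dict(DEFAULT_ORIGINAL_N)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must lie in (0, 1), got {self.ci_level}")


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"analysis stage {name!r} failed: {exc}") from exc
            return False

    return _StageContext()


class _StageError(RuntimeError):
    pass


def analyze_study(
    records: Sequence[ParticipantRecord],
    qs: QuestionSet | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> ReplicationReport:
    """Run the full pipeline: clean, score, test within and between conditions, judge.

    Deterministic: identical inputs and config yield an identical report.
    Stage failures are re-raised with the stage name attached.
    """
    qs = qs or QuestionSet.default()
    with _stage("cleaning"):
        retained, log = clean_cohort(records, config.cleaning, qs)
    with _stage("scoring"):
        acc = accuracy_table(retained, qs, log)
    with _stage("within-condition tests"):
        cond_reports: dict[str, ConditionReport] = {}
        for cond in CONDITIONS:
            sub = acc[acc["condition"] == cond]
            if len(sub) >= 2:
                cond_reports[cond] = within_condition_tests(
                    sub.reset_index(drop=True), config.ci_level, config.bf_scale
                )
    with _stage("verdicts"):
        for cond, rep in cond_reports.items():
            cond_reports[cond] = evaluate_replication(
                rep, config.original_n.get(cond), config.alpha
            )
    with _stage("between-condition tests"):
        between: dict[str, BetweenConditionResult] = {}
        if "immediate" in cond_reports and "delayed" in cond_reports:
            acc_imm = acc[acc["condition"] == "immediate"]
            acc_del = acc[acc["condition"] == "delayed"]
            for ref in ("guess1", "guess2"):
                between[ref] = between_condition_test(
                    acc_imm, acc_del, ref, config.ci_level, config.bf_scale
                )
    return ReplicationReport(
        conditions=cond_reports,
        between=between,
        alpha=config.alpha,
        ci_level=config.ci_level,
        bf_scale=config.bf_scale,
        exclusions=log,
    )
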