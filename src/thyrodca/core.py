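"""Diagnostic performance and beneficial-score analysis of thyroid-nodule
ultrasound calls against fine-needle-aspiration (FNA) cytology.

The analysis pipeline mirrors a retrospective diagnostic study design: a
cohort of thyroid nodules, each with a binary FNA reference class
(malignant / benign) and binary "suspicious" / "benign" calls from up to
three ultrasound readings (grayscale, subjective color Doppler, and the
two combined).  The module is organised in the order the analysis runs:

1.  Configuration & shared constants (modalities, rounding, the embedded
    published confusion-count fixture).
2.  Cohort synthesis — a generator for nodule-level cohorts with
    configurable prevalence, per-modality operating profiles and
    cross-modality agreement, plus a deterministic cohort that reproduces
    the published per-modality confusion counts exactly.
3.  Confusion metrics — per-modality 2x2 tables against the FNA
    reference, the study's diagnostic parameters (its "sensitivity" and
    "accuracy"), standard synonyms, and the significance tests
    (continuity-corrected chi-square, Welch t).
4.  Beneficial score — a net-benefit statistic over a grid of
    diagnosis-confidence thresholds, with closed-form solvers for each
    modality's useful threshold range.
5.  IO & pipeline — CSV readers/writers, the end-to-end report.

A note on column semantics: the published table labels the count of
FNA-malignant nodules that imaging called benign "false positive
suspicious malignant nodules detected" (standard false negatives), and
the count of FNA-benign nodules imaging called suspicious "false
positive benign nodules detected" (standard false positives).  Only this
reading makes the rows sum to the FNA margins, so :class:`ConfusionTable`
stores the original column names and exposes standard ``fn`` / ``fp``
synonyms.  Likewise the study's "accuracy" is standard specificity.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MODALITIES",
    "FNA_CLASSES",
    "CALL_VALUES",
    "COHORT_COLUMNS",
    "DEFAULT_GRID",
    "TABLE2_FIXTURE",
    "FNA_MALIGNANT_TOTAL",
    "FNA_BENIGN_TOTAL",
    "COHORT_N_TOTAL",
    "round_half_up",
    "SynthConfig",
    "NoduleRecord",
    "generate_cohort",
    "exact_paper_cohort",
    "summarize_sizes",
    "ConfusionTable",
    "DiagnosticSummary",
    "build_confusion",
    "sensitivity",
    "accuracy_paper",
    "standard_metrics",
    "yates_chi_square_vs_reference",
    "welch_t_test",
    "welch_t_from_stats",
    "StrategyCounts",
    "BeneficialCurve",
    "UsefulRange",
    "risk_of_underdiagnosis",
    "beneficial_score",
    "beneficial_curve",
    "upper_threshold",
    "lower_threshold",
    "useful_range",
    "biopsy_all_strategy",
    "strategy_from_confusion",
    "write_cohort",
    "read_cohort",
    "write_confusion_csv",
    "read_confusion_csv",
    "AnalysisReport",
    "run_pipeline",
]

# ---------------------------------------------------------------------------
# 1. Configuration, logging and shared constants
# ---------------------------------------------------------------------------

logger = logging.getLogger("thyrodca")

#: Ultrasound reading modalities, in report order.
MODALITIES: tuple[str, ...] = ("grayscale", "doppler", "combined")

FNA_CLASSES: tuple[str, str] = ("malignant", "benign")
CALL_VALUES: tuple[str, str] = ("suspicious", "benign")

#: Fixed cohort CSV header (one nodule per row).
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "nodule_id",
    "size_cm",
    "fna_class",
    "call_grayscale",
    "call_doppler",
    "call_combined",
)

#: Default diagnosis-confidence grid for beneficial-score curves.
DEFAULT_GRID: np.ndarray = np.round(np.arange(0.0, 0.951, 0.01), 10)

#: FNA reference margins of the published cohort.
FNA_MALIGNANT_TOTAL = 55
FNA_BENIGN_TOTAL = 270
COHORT_N_TOTAL = 325
COHORT_N_PATIENTS = 250

#: Published nodule-size summary (cm), grayscale vs Doppler arms.
SIZE_SUMMARY = {
    "grayscale": (1.54, 0.16),
    "doppler": (1.56, 0.17),
}


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` half away from zero to ``ndigits`` decimals.

    Published tables use commercial half-up rounding, not banker's
    rounding, so ``round()`` is not a drop-in (e.g. 0.0635 -> 0.064).
    NaN passes through unchanged.
    """
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# 2. Cohort synthesis
# ---------------------------------------------------------------------------


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic nodule cohort.

    Attributes
    ----------
    n_nodules, n_patients:
        Cohort size; each patient carries 1–4 nodules, so
        ``n_patients <= n_nodules <= 4 * n_patients``.
    prevalence:
        FNA-malignant fraction (55/325 in the emulated study).
    modality_profiles:
        Map modality name -> ``(p_suspicious_given_malignant,
        p_suspicious_given_benign)`` — the true-positive and
        false-positive call rates of each reading.
    agreement:
        Cross-modality coupling in [0, 1]: probability that a modality's
        call is driven by a nodule-level shared latent uniform rather
        than an independent one.  0 = independent calls, 1 = comonotone
        (identical profiles then give identical call vectors).
    size_mean_cm, size_sd_cm:
        Nodule-size distribution, normal truncated at zero.
    seed:
        Seed for all randomness; identical configs give byte-identical
        cohorts.
    """

    n_nodules: int = COHORT_N_TOTAL
    n_patients: int = COHORT_N_PATIENTS
    prevalence: float = FNA_MALIGNANT_TOTAL / COHORT_N_TOTAL
    modality_profiles: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "grayscale": (31 / 55, 20 / 270),
            "doppler": (33 / 55, 22 / 270),
            "combined": (38 / 55, 11 / 270),
        }
    )
    agreement: float = 0.7
    size_mean_cm: float = 1.55
    size_sd_cm: float = 0.165
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_nodules, int) or self.n_nodules < 1:
            raise ValueError(f"n_nodules must be a positive integer, got {self.n_nodules!r}")
        if not isinstance(self.n_patients, int) or self.n_patients < 1:
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        if self.n_nodules < self.n_patients:
            raise ValueError(
                f"n_nodules ({self.n_nodules}) must be >= n_patients ({self.n_patients})"
            )
        if self.n_nodules > 4 * self.n_patients:
            raise ValueError(
                f"n_nodules ({self.n_nodules}) exceeds 4 nodules per patient "
                f"({self.n_patients} patients)"
            )
        _check_prob("prevalence", self.prevalence)
        _check_prob("agreement", self.agreement)
        if not self.modality_profiles:
            raise ValueError("modality_profiles must name at least one modality")
        for name, profile in self.modality_profiles.items():
            if len(profile) != 2:
                raise ValueError(f"modality_profiles[{name!r}] must be a (p_tp, p_fp) pair")
            _check_prob(f"modality_profiles[{name!r}][0]", profile[0])
            _check_prob(f"modality_profiles[{name!r}][1]", profile[1])
        if self.size_sd_cm <= 0:
            raise ValueError(f"size_sd_cm must be > 0, got {self.size_sd_cm!r}")
        if self.size_mean_cm <= 0:
            raise ValueError(f"size_mean_cm must be > 0, got {self.size_mean_cm!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "n_nodules": self.n_nodules,
                "n_patients": self.n_patients,
                "prevalence": self.prevalence,
                "modality_profiles": {k: list(v) for k, v in sorted(self.modality_profiles.items())},
                "agreement": self.agreement,
                "size_mean_cm": self.size_mean_cm,
                "size_sd_cm": self.size_sd_cm,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class NoduleRecord:
    """One thyroid nodule: the unit of analysis.

    ``calls`` maps modality name -> "suspicious" | "benign".
    ``annotations`` carries inert patient-level demographics (age,
    gender, ethnicity, family history); no statistic in this package
    uses them.
    """

    patient_id: str
    nodule_id: str
    size_cm: float
    fna_class: str
    calls: dict[str, str]
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fna_class not in FNA_CLASSES:
            raise ValueError(
                f"fna_class must be one of {FNA_CLASSES}, got {self.fna_class!r} "
                f"(nodule {self.nodule_id})"
            )
        for modality, call in self.calls.items():
            if call not in CALL_VALUES:
                raise ValueError(
                    f"call for {modality!r} must be one of {CALL_VALUES}, got {call!r} "
                    f"(nodule {self.nodule_id})"
                )
        if not (self.size_cm > 0):
            raise ValueError(f"size_cm must be > 0, got {self.size_cm!r} (nodule {self.nodule_id})")


def _nodules_per_patient(rng: np.random.Generator, n_patients: int, n_nodules: int) -> np.ndarray:
    """Draw per-patient nodule counts in 1–4 summing exactly to ``n_nodules``.

    Counts follow a geometric distribution capped at 4 with success
    probability 1/1.3 (mean ~1.3 nodules per patient before the exact-sum
    adjustment), then greedy +/-1 adjustments pin the total.
    """
    p = 1.0 / 1.3
    pmf = np.array([p * (1 - p) ** (k - 1) for k in range(1, 5)])
    pmf /= pmf.sum()
    counts = rng.choice(np.arange(1, 5), size=n_patients, p=pmf)
    diff = int(n_nodules - counts.sum())
    idx = rng.permutation(n_patients)
    i = 0
    while diff != 0:
        j = idx[i % n_patients]
        if diff > 0 and counts[j] < 4:
            counts[j] += 1
            diff -= 1
        elif diff < 0 and counts[j] > 1:
            counts[j] -= 1
            diff += 1
        i += 1
    return counts


def _demographics(rng: np.random.Generator, n_patients: int) -> list[dict[str, object]]:
    """Inert patient-level annotations emulating the published cohort's
    marginals (age 19–71, mean 48.55 SD 7.54; 79% female; 91/8/1%
    Han/Mongolian/Tibetan; 5% family history)."""
    age_lo, age_hi, age_mu, age_sd = 19, 71, 48.55, 7.54
    a, b = (age_lo - age_mu) / age_sd, (age_hi - age_mu) / age_sd
    ages = stats.truncnorm.rvs(a, b, loc=age_mu, scale=age_sd, size=n_patients, random_state=rng)
    female = rng.random(n_patients) < 197 / 250
    ethnicity = rng.choice(
        ["han_chinese", "mongolian", "tibetan"], size=n_patients, p=[227 / 250, 20 / 250, 3 / 250]
    )
    family_history = rng.random(n_patients) < 12 / 250
    return [
        {
            "age_years": round(float(ages[i]), 1),
            "gender": "female" if female[i] else "male",
            "ethnicity": str(ethnicity[i]),
            "family_history": bool(family_history[i]),
        }
        for i in range(n_patients)
    ]


def generate_cohort(config: SynthConfig) -> list[NoduleRecord]:
    """Generate a synthetic nodule cohort under ``config``.

    Per nodule: the FNA class is Bernoulli(prevalence); each modality
    calls "suspicious" when a uniform variate falls below the profile
    rate for that class, with the variate shared across modalities with
    probability ``agreement`` (rank coupling between independence and
    comonotone calls); sizes are normal truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    modalities = list(config.modality_profiles)

    counts = _nodules_per_patient(rng, config.n_patients, config.n_nodules)
    patient_ids = [f"p{i + 1:04d}" for i in range(config.n_patients)]
    demographics = dict(zip(patient_ids, _demographics(rng, config.n_patients)))
    patient_of = np.repeat(np.arange(config.n_patients), counts)

    n = config.n_nodules
    malignant = rng.random(n) < config.prevalence
    u_shared = rng.random(n)
    a_, b_ = -config.size_mean_cm / config.size_sd_cm, np.inf
    sizes = stats.truncnorm.rvs(
        a_, b_, loc=config.size_mean_cm, scale=config.size_sd_cm, size=n, random_state=rng
    )

    calls_by_modality: dict[str, np.ndarray] = {}
    for modality in modalities:
        p_tp, p_fp = config.modality_profiles[modality]
        use_shared = rng.random(n) < config.agreement
        u = np.where(use_shared, u_shared, rng.random(n))
        p_call = np.where(malignant, p_tp, p_fp)
        calls_by_modality[modality] = u < p_call

    records: list[NoduleRecord] = []
    for i in range(n):
        pid = patient_ids[patient_of[i]]
        records.append(
            NoduleRecord(
                patient_id=pid,
                nodule_id=f"n{i + 1:04d}",
                size_cm=float(sizes[i]),
                fna_class="malignant" if malignant[i] else "benign",
                calls={
                    m: "suspicious" if calls_by_modality[m][i] else "benign" for m in modalities
                },
                annotations=dict(demographics[pid]),
            )
        )
    return records


#: Published per-modality confusion counts, in the column order
#: (tp_suspicious, tp_benign, fp_suspicious_col, fp_benign_col).
_TABLE2_CELLS: dict[str, tuple[int, int, int, int]] = {
    "grayscale": (31, 250, 24, 20),
    "doppler": (33, 248, 22, 22),
    "combined": (38, 259, 17, 11),
}


def exact_paper_cohort() -> list[NoduleRecord]:
    """Deterministic 325-nodule cohort reproducing the published
    per-modality confusion counts cell-for-cell.

    The per-modality margins underdetermine the cross-modality joint
    distribution; this construction uses maximal overlap: within the 55
    FNA-malignant nodules the combined modality's 38 suspicious calls
    contain the Doppler 33, which contain the grayscale 31; within the
    270 FNA-benign nodules the Doppler 22 over-calls contain the
    grayscale 20 and the combined 11.  All per-modality statistics are
    invariant to this choice.

    Sizes are deterministic truncated-normal quantiles (mean 1.55 cm,
    SD 0.165 cm); 75 of the 250 patients carry two nodules (mean 1.3).
    """
    tp = {m: _TABLE2_CELLS[m][0] for m in MODALITIES}  # suspicious among 55 malignant
    fp = {m: _TABLE2_CELLS[m][3] for m in MODALITIES}  # suspicious among 270 benign

    a_ = -1.55 / 0.165
    # evenly spaced quantiles of the size distribution -> deterministic sizes
    qs = (np.arange(COHORT_N_TOTAL) + 0.5) / COHORT_N_TOTAL
    sizes = stats.truncnorm.ppf(qs, a_, np.inf, loc=1.55, scale=0.165)
    # interleave so malignant/benign blocks get similar size spreads
    order = np.argsort(np.tile(np.arange(5), 65), kind="stable")
    sizes = sizes[order]

    records: list[NoduleRecord] = []
    for i in range(COHORT_N_TOTAL):
        is_malignant = i < FNA_MALIGNANT_TOTAL
        j = i if is_malignant else i - FNA_MALIGNANT_TOTAL
        calls = {}
        for m in MODALITIES:
            cut = tp[m] if is_malignant else fp[m]
            calls[m] = "suspicious" if j < cut else "benign"
        # patients 1..175 carry one nodule, 176..250 carry two
        patient_idx = i if i < 175 else 175 + (i - 175) // 2
        records.append(
            NoduleRecord(
                patient_id=f"p{patient_idx + 1:04d}",
                nodule_id=f"n{i + 1:04d}",
                size_cm=float(sizes[i]),
                fna_class="malignant" if is_malignant else "benign",
                calls=calls,
            )
        )
    return records


def summarize_sizes(
    records: Sequence[NoduleRecord],
    modality: str | None = None,
    call: str = "suspicious",
) -> tuple[float, float, int]:
    """Sample mean and SD (n-1 denominator) of nodule sizes in cm.

    With ``modality`` given, restricts to nodules that modality called
    ``call``.  Returns ``(mean, sd, n)``; ``sd`` is NaN when n < 2.
    """
    if not records:
        raise ValueError("summarize_sizes requires a nonempty record collection")
    if modality is not None:
        records = [r for r in records if r.calls.get(modality) == call]
        if not records:
            raise ValueError(f"no records with {modality!r} call == {call!r}")
    sizes = np.array([r.size_cm for r in records], dtype=float)
    n = sizes.size
    mean = float(sizes.mean())
    sd = float(sizes.std(ddof=1)) if n > 1 else math.nan
    return mean, sd, n


# ---------------------------------------------------------------------------
# 3. Confusion metrics and significance tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """Per-modality confusion counts against the FNA reference.

    Field names keep the published column labels; the standard synonyms
    are exposed as properties: ``fp_suspicious_col`` counts FNA-malignant
    nodules the modality called benign (standard false negatives, ``fn``)
    and ``fp_benign_col`` counts FNA-benign nodules called suspicious
    (standard false positives, ``fp``).
    """

    modality: str
    tp_suspicious: int
    tp_benign: int
    fp_suspicious_col: int
    fp_benign_col: int
    n_total: int

    def __post_init__(self) -> None:
        cells = (self.tp_suspicious, self.tp_benign, self.fp_suspicious_col, self.fp_benign_col)
        if any(c < 0 for c in cells):
            raise ValueError(f"confusion cells must be >= 0, got {cells}")
        if sum(cells) != self.n_total:
            raise ValueError(
                f"confusion cells {cells} sum to {sum(cells)}, expected n_total={self.n_total}"
            )

    # standard synonyms
    @property
    def tp(self) -> int:
        return self.tp_suspicious

    @property
    def tn(self) -> int:
        return self.tp_benign

    @property
    def fn(self) -> int:
        """FNA-malignant nodules the modality called benign."""
        return self.fp_suspicious_col

    @property
    def fp(self) -> int:
        """FNA-benign nodules the modality called suspicious."""
        return self.fp_benign_col

    @property
    def n_malignant(self) -> int:
        return self.tp_suspicious + self.fp_suspicious_col

    @property
    def n_benign(self) -> int:
        return self.tp_benign + self.fp_benign_col


@dataclass(frozen=True)
class DiagnosticSummary:
    """The study's diagnostic parameters plus standard synonyms.

    ``sensitivity`` and ``accuracy_paper`` follow the study's
    definitions (TP-suspicious over FNA-malignant; TP-benign over
    FNA-benign — the latter is standard specificity).  Undefined ratios
    (zero denominator) are NaN.
    """

    modality: str
    sensitivity: float
    accuracy_paper: float
    specificity_std: float
    ppv_std: float
    npv_std: float


def build_confusion(records: Sequence[NoduleRecord], modality: str) -> ConfusionTable:
    """Partition ``records`` into the four confusion cells for ``modality``."""
    if not records:
        raise ValueError("build_confusion requires a nonempty record collection")
    cells = {"tp_suspicious": 0, "tp_benign": 0, "fp_suspicious_col": 0, "fp_benign_col": 0}
    for r in records:
        if modality not in r.calls:
            raise ValueError(f"record {r.nodule_id!r} has no call for modality {modality!r}")
        suspicious = r.calls[modality] == "suspicious"
        if r.fna_class == "malignant":
            cells["tp_suspicious" if suspicious else "fp_suspicious_col"] += 1
        else:
            cells["fp_benign_col" if suspicious else "tp_benign"] += 1
    return ConfusionTable(modality=modality, n_total=len(records), **cells)


def sensitivity(ct: ConfusionTable) -> float:
    """TP-suspicious over all FNA-malignant nodules; NaN when none."""
    denom = ct.n_malignant
    if denom == 0:
        logger.warning("sensitivity undefined for %s: no FNA-malignant nodules", ct.modality)
        return math.nan
    return ct.tp_suspicious / denom


def accuracy_paper(ct: ConfusionTable) -> float:
    """TP-benign over all FNA-benign nodules (standard specificity);
    NaN when the cohort has no FNA-benign nodules."""
    denom = ct.n_benign
    if denom == 0:
        logger.warning("accuracy undefined for %s: no FNA-benign nodules", ct.modality)
        return math.nan
    return ct.tp_benign / denom


def standard_metrics(ct: ConfusionTable) -> DiagnosticSummary:
    """Diagnostic summary under both the study's and standard semantics."""

    def ratio(num: int, denom: int, name: str) -> float:
        if denom == 0:
            logger.warning("%s undefined for %s: zero denominator", name, ct.modality)
            return math.nan
        return num / denom

    return DiagnosticSummary(
        modality=ct.modality,
        sensitivity=sensitivity(ct),
        accuracy_paper=accuracy_paper(ct),
        specificity_std=ratio(ct.tn, ct.n_benign, "specificity"),
        ppv_std=ratio(ct.tp, ct.tp + ct.fp, "ppv"),
        npv_std=ratio(ct.tn, ct.tn + ct.fn, "npv"),
    )


def yates_chi_square_vs_reference(
    count_modality: int, count_reference: int, n_per_arm: int
) -> tuple[float, float]:
    """Continuity-corrected chi-square comparing a modality's count of
    detections against the FNA reference count, each out of ``n_per_arm``
    nodules.

    Builds the 2x2 table ``[[c_m, n - c_m], [c_ref, n - c_ref]]`` and
    returns the Yates-corrected statistic with its df=1 upper-tail
    probability.  The correction is required to reproduce the published
    p-values.
    """
    for name, c in (("count_modality", count_modality), ("count_reference", count_reference)):
        if not (0 <= c <= n_per_arm):
            raise ValueError(f"{name} must be in [0, n_per_arm], got {c} with n={n_per_arm}")
    table = np.array(
        [
            [count_modality, n_per_arm - count_modality],
            [count_reference, n_per_arm - count_reference],
        ]
    )
    if (table.sum(axis=0) == 0).any():
        raise ValueError(f"degenerate 2x2 table (a zero expected cell): {table.tolist()}")
    if count_modality == count_reference:
        # identical proportions: correction would otherwise overshoot
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Welch unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"welch_t_test needs >= 2 observations per sample, got {a.size} and {b.size}")
    if a.size == b.size and np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def welch_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Welch t-test from summary statistics (mean, SD, n per arm)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("welch_t_from_stats needs n >= 2 per arm")
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# 4. Beneficial score (net benefit over diagnosis-confidence thresholds)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyCounts:
    """Counts feeding the beneficial score for one decision strategy.

    For an imaging modality ``tp`` is its TP-suspicious count and ``fp``
    its published "false positive suspicious" column (missed
    malignancies under standard semantics — this convention is what
    reproduces the published upper bounds).  For the biopsy-all
    reference strategy ``tp`` is all FNA-malignant nodules and ``fp``
    all FNA-benign nodules, so ``tp + fp <= n`` is deliberately not
    required.
    """

    label: str
    tp: int
    fp: int
    n: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError(f"tp and fp must be >= 0, got tp={self.tp}, fp={self.fp}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")


@dataclass(frozen=True)
class BeneficialCurve:
    """Beneficial score evaluated over a threshold grid for one strategy."""

    strategy: str
    points: tuple[tuple[float, float], ...]

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.points])


@dataclass(frozen=True)
class UsefulRange:
    """Diagnosis-confidence interval in which a modality is useful.

    Below ``lower`` the modality scores under the biopsy-all reference
    (risk of overdiagnosis); above ``upper`` its score is non-positive
    (no diagnostic potential).
    """

    strategy: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.lower) or math.isnan(self.upper)) and self.lower > self.upper:
            raise ValueError(
                f"useful range inverted for {self.strategy}: lower {self.lower} > upper {self.upper}"
            )

    def printed(self) -> dict[str, float]:
        """Both 2- and 3-decimal printed forms of each bound."""
        return {
            "lower_2dp": round_half_up(self.lower, 2),
            "lower_3dp": round_half_up(self.lower, 3),
            "upper_2dp": round_half_up(self.upper, 2),
            "upper_3dp": round_half_up(self.upper, 3),
        }


def risk_of_underdiagnosis(threshold: float) -> float:
    """Odds transform ``t / (1 - t)`` of a diagnosis-confidence threshold.

    The weight on false positives in the beneficial score: how many
    false positives one true positive is worth at confidence ``t``.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold!r}")
    return threshold / (1.0 - threshold)


def beneficial_score(s: StrategyCounts, threshold: float) -> float:
    """Net benefit of strategy ``s`` at a diagnosis-confidence threshold:
    ``tp/n - (fp/n) * threshold / (1 - threshold)``."""
    w = risk_of_underdiagnosis(threshold)
    return s.tp / s.n - (s.fp / s.n) * w


def beneficial_curve(s: StrategyCounts, grid: Sequence[float]) -> BeneficialCurve:
    """Evaluate the beneficial score over a strictly increasing grid in [0, 1)."""
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("threshold grid is empty")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise ValueError("threshold grid must be strictly increasing")
    if g[0] < 0 or g[-1] >= 1:
        raise ValueError("threshold grid must lie within [0, 1)")
    scores = s.tp / s.n - (s.fp / s.n) * g / (1.0 - g)
    return BeneficialCurve(strategy=s.label, points=tuple(zip(g.tolist(), scores.tolist())))


def upper_threshold(s: StrategyCounts) -> float:
    """Threshold above which the strategy's score is non-positive.

    Closed form ``tp / (tp + fp)`` (the root of the score in the
    threshold); 1 when ``fp == 0`` (score never reaches zero); NaN flag
    when ``tp == 0`` (useful range empty).
    """
    if s.tp == 0:
        logger.warning("upper_threshold: %s has tp=0, useful range is empty", s.label)
        return math.nan
    if s.fp == 0:
        return 1.0
    return s.tp / (s.tp + s.fp)


def lower_threshold(s: StrategyCounts, biopsy_all: StrategyCounts) -> float:
    """Threshold at which the strategy's score crosses the biopsy-all
    reference score.

    Setting the two scores equal gives odds
    ``(tp_all - tp) / (fp_all - fp)`` and threshold ``odds / (1 + odds)``;
    0 when the strategy detects every malignancy the reference does.
    Returns a NaN flag when the reference has no false-positive excess
    (no crossover exists).
    """
    if biopsy_all.tp < s.tp:
        raise ValueError(
            f"reference strategy detects fewer malignancies ({biopsy_all.tp}) than "
            f"{s.label} ({s.tp})"
        )
    if s.tp == biopsy_all.tp:
        # detects everything the reference does: never scores below it
        return 0.0
    if biopsy_all.fp <= s.fp:
        logger.warning(
            "lower_threshold: reference fp (%d) <= strategy fp (%d), no crossover",
            biopsy_all.fp,
            s.fp,
        )
        return math.nan
    odds = (biopsy_all.tp - s.tp) / (biopsy_all.fp - s.fp)
    return odds / (1.0 + odds)


def useful_range(s: StrategyCounts, biopsy_all: StrategyCounts) -> UsefulRange:
    """The (lower, upper) diagnosis-confidence interval in which ``s``
    outperforms both biopsy-all and biopsy-none."""
    return UsefulRange(
        strategy=s.label,
        lower=lower_threshold(s, biopsy_all),
        upper=upper_threshold(s),
    )


def biopsy_all_strategy(
    n_malignant: int = FNA_MALIGNANT_TOTAL,
    n_benign: int = FNA_BENIGN_TOTAL,
    label: str = "biopsy_all",
) -> StrategyCounts:
    """Reference strategy that aspirates every nodule: it detects every
    FNA-malignant nodule (tp) and biopsies every FNA-benign one (fp)."""
    return StrategyCounts(label=label, tp=n_malignant, fp=n_benign, n=n_malignant + n_benign)


def strategy_from_confusion(ct: ConfusionTable) -> StrategyCounts:
    """Strategy counts for an imaging modality: tp = TP-suspicious, fp =
    the published "false positive suspicious" column (= missed
    malignancies under standard semantics; the convention the published
    bounds pin down)."""
    return StrategyCounts(label=ct.modality, tp=ct.tp_suspicious, fp=ct.fp_suspicious_col, n=ct.n_total)


# ---------------------------------------------------------------------------
# 5. IO, fixtures and the end-to-end pipeline
# ---------------------------------------------------------------------------

#: Embedded published confusion counts as ConfusionTable objects.
TABLE2_FIXTURE: dict[str, ConfusionTable] = {
    m: ConfusionTable(m, *_TABLE2_CELLS[m], n_total=COHORT_N_TOTAL) for m in MODALITIES
}

CONFUSION_CSV_COLUMNS = ("modality", "tp_suspicious", "tp_benign", "fp_suspicious", "fp_benign", "n_total")


def write_cohort(records: Sequence[NoduleRecord], path) -> None:
    """Write a cohort as CSV with the fixed column schema."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.nodule_id,
                    f"{r.size_cm:.6g}",
                    r.fna_class,
                    r.calls.get("grayscale", ""),
                    r.calls.get("doppler", ""),
                    r.calls.get("combined", ""),
                ]
            )


def read_cohort(path) -> list[NoduleRecord]:
    """Read and validate a cohort CSV.

    Enum fields are case-normalized ("Malignant" -> "malignant"); a
    malformed row raises with its line number, an unknown enum value
    raises naming the value.
    """
    records: list[NoduleRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if tuple(header) != COHORT_COLUMNS:
            missing = set(COHORT_COLUMNS) - set(header)
            extra = set(header) - set(COHORT_COLUMNS)
            raise ValueError(
                f"{path}: header mismatch (missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(COHORT_COLUMNS)} fields, got {len(row)}")
            pid, nid, size_s, fna, g, d, c = (v.strip() for v in row)
            try:
                size = float(size_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: size_cm is not numeric: {size_s!r}") from None
            fna = fna.lower()
            calls = {"grayscale": g.lower(), "doppler": d.lower(), "combined": c.lower()}
            try:
                records.append(
                    NoduleRecord(patient_id=pid, nodule_id=nid, size_cm=size, fna_class=fna, calls=calls)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    seen: set[str] = set()
    for r in records:
        if r.nodule_id in seen:
            raise ValueError(f"{path}: duplicate nodule_id {r.nodule_id!r}")
        seen.add(r.nodule_id)
    return records


def write_confusion_csv(tables: Mapping[str, ConfusionTable], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONFUSION_CSV_COLUMNS)
        for ct in tables.values():
            writer.writerow(
                [ct.modality, ct.tp_suspicious, ct.tp_benign, ct.fp_suspicious_col, ct.fp_benign_col, ct.n_total]
            )


def read_confusion_csv(path) -> dict[str, ConfusionTable]:
    tables: dict[str, ConfusionTable] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CONFUSION_CSV_COLUMNS:
            raise ValueError(f"{path}: header must be {','.join(CONFUSION_CSV_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ct = ConfusionTable(
                    modality=row["modality"].strip(),
                    tp_suspicious=int(row["tp_suspicious"]),
                    tp_benign=int(row["tp_benign"]),
                    fp_suspicious_col=int(row["fp_suspicious"]),
                    fp_benign_col=int(row["fp_benign"]),
                    n_total=int(row["n_total"]),
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            tables[ct.modality] = ct
    return tables


@dataclass
class AnalysisReport:
    """End-to-end analysis results: per-modality confusion tables,
    diagnostic summaries, chi-square comparisons against the FNA
    reference, beneficial-score useful ranges, and provenance."""

    confusion: dict[str, ConfusionTable]
    diagnostics: dict[str, DiagnosticSummary]
    chi_square: dict[str, dict[str, dict[str, float]]]
    ranges: dict[str, UsefulRange]
    curves: dict[str, BeneficialCurve]
    provenance: dict[str, object]

    def as_dict(self) -> dict:
        out = {
            "confusion": {m: asdict(ct) for m, ct in self.confusion.items()},
            "diagnostics": {
                m: {
                    k: (round_half_up(v, 3) if isinstance(v, float) else v)
                    for k, v in asdict(d).items()
                }
                for m, d in self.diagnostics.items()
            },
            "chi_square": self.chi_square,
            "ranges": {
                m: {"lower": r.lower, "upper": r.upper, **r.printed()} for m, r in self.ranges.items()
            },
            "provenance": self.provenance,
        }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent, default=str)

    def to_text(self) -> str:
        lines = ["Thyroid-nodule ultrasound vs FNA cytology — analysis report", ""]
        lines.append(f"{'modality':<12}{'sens':>8}{'acc':>8}{'spec':>8}{'ppv':>8}{'npv':>8}")
        for m, d in self.diagnostics.items():
            lines.append(
                f"{m:<12}{round_half_up(d.sensitivity, 3):>8}{round_half_up(d.accuracy_paper, 3):>8}"
                f"{round_half_up(d.specificity_std, 3):>8}{round_half_up(d.ppv_std, 3):>8}"
                f"{round_half_up(d.npv_std, 3):>8}"
            )
        lines.append("")
        lines.append("Useful diagnosis-confidence ranges (beneficial score):")
        for m, r in self.ranges.items():
            p = r.printed()
            lines.append(
                f"  {m:<12} lower {p['lower_2dp']} ({p['lower_3dp']})  upper {p['upper_2dp']} ({p['upper_3dp']})"
            )
        lines.append("")
        lines.append("Chi-square vs FNA reference (Yates-corrected):")
        for m, rows in self.chi_square.items():
            for row_name, res in rows.items():
                lines.append(
                    f"  {m:<12} {row_name:<22} chi2={res['chi2']:.3f}  p={round_half_up(res['p'], 3)}"
                )
        return "\n".join(lines)


def run_pipeline(
    records: Sequence[NoduleRecord] | None = None,
    tables: Mapping[str, ConfusionTable] | None = None,
    grid: Sequence[float] | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> AnalysisReport:
    """Run the full analysis on nodule records or pre-aggregated
    confusion counts (exactly one of ``records`` / ``tables``).

    Computes per-modality diagnostics, Yates chi-square comparisons of
    each modality's detection counts against the FNA reference,
    beneficial-score curves over ``grid`` (default 0–0.95 step 0.01) and
    each modality's useful threshold range against the biopsy-all
    reference strategy.
    """
    if (records is None) == (tables is None):
        raise ValueError("run_pipeline needs exactly one of records or tables")
    if records is not None:
        modalities = list(records[0].calls) if records else []
        tables = {m: build_confusion(records, m) for m in modalities}

    assert tables is not None
    grid_arr = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    logger.info(
        "pipeline toggles: fp_convention=paper-column, rounding=half-up-3dp, "
        "grid=[%g..%g step %g], yates=True",
        grid_arr[0],
        grid_arr[-1],
        grid_arr[1] - grid_arr[0] if grid_arr.size > 1 else 0.0,
    )

    diagnostics = {m: standard_metrics(ct) for m, ct in tables.items()}

    chi: dict[str, dict[str, dict[str, float]]] = {}
    for m, ct in tables.items():
        n = ct.n_total
        chi[m] = {}
        for row_name, c_mod, c_ref in (
            ("tp_suspicious", ct.tp_suspicious, ct.n_malignant),
            ("tp_benign", ct.tp_benign, ct.n_benign),
        ):
            try:
                chi2, p = yates_chi_square_vs_reference(c_mod, c_ref, n)
                chi[m][row_name] = {"chi2": chi2, "p": p}
            except ValueError:
                chi[m][row_name] = {"chi2": math.nan, "p": math.nan}

    any_ct = next(iter(tables.values()))
    reference = biopsy_all_strategy(any_ct.n_malignant, any_ct.n_benign)
    strategies = {m: strategy_from_confusion(ct) for m, ct in tables.items()}
    curves = {m: beneficial_curve(s, grid_arr) for m, s in strategies.items()}
    curves["biopsy_all"] = beneficial_curve(reference, grid_arr)
    ranges = {m: useful_range(s, reference) for m, s in strategies.items()}

    provenance = {
        "seed": seed,
        "config_hash": config_hash,
        "generated_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "n_total": any_ct.n_total,
        "fp_convention": "paper-column",
        "rounding": "half-up",
        "grid": [float(grid_arr[0]), float(grid_arr[-1]), float(grid_arr[1] - grid_arr[0]) if grid_arr.size > 1 else 0.0],
    }
    return AnalysisReport(
        confusion=dict(tables),
        diagnostics=diagnostics,
        chi_square=chi,
        ranges=ranges,
        curves=curves,
        provenance=provenance,
    )
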