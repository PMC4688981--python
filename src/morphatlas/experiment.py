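"""Leave-one-out selected-vs-random evaluation and its statistics.

Design: each atlas in the database plays the patient in turn; the remaining
atlases form the candidate pool.  In the *selected* arm, the k atlases with
protraction distances closest to the patient's are propagated onto the
patient, STAPLE-fused, and scored against the patient's gold standard; in
the *random* arm, combinations of k atlases are drawn uniformly from the
pool instead.  k ranges over 2..8 by default, so a 12-atlas database yields
7 x 12 = 84 selected-arm runs.

Statistics mirror a two-arm accuracy comparison: per-k group means and SDs,
a Welch independent-sample t-test between arms, an equivalence trial on the
mean DSC difference between a reference atlas count and its neighbours
(two-sided 90% CI within a pre-set margin), and the standard two-group
normal-approximation sample-size formula.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .fusion import FusionConfig, staple_from_config
from .metrics import SimilarityScores, score_pair
from .morphometry import AtlasRecord, rank_atlases, select_top_k
from .synthetic import PhantomAtlas, SyntheticConfig, simulate_registration
from .volume import LabelVolume

logger = logging.getLogger(__name__)

#: A registration backend: (atlas, patient, seed) -> propagated label volume.
Registration = Callable[[AtlasRecord, AtlasRecord, int], LabelVolume]


@dataclass
class ExperimentConfig:
    """Settings of the leave-one-out experiment.

    ``random_limit`` caps the number of random combinations per (patient, k);
    the default of 7 gives 12 x 7 = 84 runs per k on a 12-atlas database,
    clearing the 75-runs-per-k sample-size requirement.  ``"all"`` enumerates
    every combination.
    """

    k_values: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    random_limit: int | str = 7
    margin_mode: str = "relative"
    margin_value: float = 0.10
    confidence: float = 0.90
    alpha: float = 0.10
    power: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown margin_mode {self.margin_mode!r}")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")


@dataclass
class RunRecord:
    """One fused-and-scored combination of the design."""

    patient_id: str
    k: int
    strategy: str  # "selected" | "random"
    combination: frozenset[str]
    scores: SimilarityScores

    def __post_init__(self) -> None:
        if self.k != len(self.combination):
            raise ValueError("k must equal the combination size")
        if self.patient_id in self.combination:
            raise ValueError("patient must not appear in its own atlas set")


@dataclass
class GroupSummary:
    """Per-(strategy, k) mean and sample SD of each similarity index."""

    strategy: str
    k: int
    n_runs: int
    dsc_mean: float
    dsc_sd: float
    ji_mean: float
    ji_sd: float
    ini_mean: float
    ini_sd: float
    sd_defined: bool = True


@dataclass
class EquivalenceResult:
    """Outcome of one equivalence comparison on mean DSC."""

    reference_k: int
    comparison_k: int
    mean_difference: float
    ci_low: float
    ci_high: float
    margin: float
    equivalent: bool


# ---------------------------------------------------------------------------
# combination enumeration and the two experimental arms
# ---------------------------------------------------------------------------

def enumerate_random_combinations(
    available: Sequence[str], k: int, limit: int | str = "all", seed: int = 0
) -> list[frozenset[str]]:
    """Distinct k-subsets of ``available``: all of them, or a seeded sample.

    With ``limit="all"`` every C(n, k) subset is returned (deterministic
    lexicographic order); otherwise ``limit`` distinct subsets are drawn
    uniformly without replacement using ``seed``.
    """
    n = len(available)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} available atlases")
    ordered = sorted(available)
    all_combos = [frozenset(c) for c in combinations(ordered, k)]
    if limit == "all" or limit >= len(all_combos):
        return all_combos
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(all_combos), size=int(limit), replace=False)
    return [all_combos[i] for i in sorted(idx)]


def _registration_seed(base_seed: int, patient_id: str, atlas_id: str) -> int:
    """Deterministic per-(patient, atlas) seed, independent of k and arm.

    Uses CRC32 of the identifiers (not Python's randomised ``hash``) so two
    processes with the same inputs produce identical runs.
    """
    ss = np.random.SeedSequence(
        [
            int(base_seed) % (2**31),
            zlib.crc32(patient_id.encode()) % (2**31),
            zlib.crc32(atlas_id.encode()) % (2**31),
        ]
    )
    return int(ss.generate_state(1)[0] % (2**31))


class PropagationCache:
    """Caches one propagated label map per (patient, atlas) pair.

    The registration of a given atlas onto a given patient does not depend
    on k or on the arm, so both arms and all atlas counts reuse the same
    propagated contours — this also guarantees that at k = n-1, where both
    arms use the single possible combination, their scores coincide exactly.
    """

    def __init__(self, registration: Registration, base_seed: int):
        self._registration = registration
        self._base_seed = base_seed
        self._cache: dict[tuple[str, str], LabelVolume] = {}

    def get(self, atlas: AtlasRecord, patient: AtlasRecord) -> LabelVolume:
        key = (patient.id, atlas.id)
        if key not in self._cache:
            seed = _registration_seed(self._base_seed, patient.id, atlas.id)
            self._cache[key] = self._registration(atlas, patient, seed)
        return self._cache[key]


def _default_registration(synthetic_config: SyntheticConfig) -> Registration:
    def register(atlas: AtlasRecord, patient: AtlasRecord, seed: int) -> LabelVolume:
        return simulate_registration(atlas, patient, synthetic_config, seed)

    return register


def _records(db: Sequence[PhantomAtlas | AtlasRecord]) -> list[AtlasRecord]:
    return [a.atlas if isinstance(a, PhantomAtlas) else a for a in db]


def _fuse_and_score(
    patient: AtlasRecord,
    members: Sequence[AtlasRecord],
    cache: PropagationCache,
    fusion_config: FusionConfig,
) -> SimilarityScores:
    propagated = [cache.get(m, patient) for m in members]
    fused = staple_from_config(propagated, fusion_config)
    return score_pair(patient.gold_mask, fused.consensus)


def run_selected_arm(
    db: Sequence[PhantomAtlas | AtlasRecord],
    k_values: Iterable[int] = (2, 3, 4, 5, 6, 7, 8),
    synthetic_config: SyntheticConfig | None = None,
    fusion_config: FusionConfig | None = None,
    registration: Registration | None = None,
    seed: int = 0,
    cache: PropagationCache | None = None,
) -> list[RunRecord]:
    """Leave-one-out runs with morphometrically selected atlases.

    For every patient and every k: rank the remaining atlases by protraction
    closeness, take the top k, propagate each onto the patient, STAPLE-fuse
    and score.  One record per (patient, k).
    """
    records = _records(db)
    k_values = sorted(k_values)
    if len(records) < max(k_values) + 1:
        raise ValueError(
            f"database of {len(records)} atlases too small for k={max(k_values)}"
        )
    fusion_config = fusion_config or FusionConfig()
    if registration is None:
        registration = _default_registration(synthetic_config or SyntheticConfig())
    cache = cache or PropagationCache(registration, seed)

    out: list[RunRecord] = []
    for patient in records:
        pool = [a for a in records if a.id != patient.id]
        ranked = rank_atlases(patient.protraction_mm, pool)
        for k in k_values:
            members = select_top_k(ranked, k)
            try:
                scores = _fuse_and_score(patient, members, cache, fusion_config)
            except Exception as exc:
                raise RuntimeError(
                    f"selected arm failed at patient={patient.id}, k={k}"
                ) from exc
            out.append(
                RunRecord(
                    patient_id=patient.id,
                    k=k,
                    strategy="selected",
                    combination=frozenset(m.id for m in members),
                    scores=scores,
                )
            )
            logger.info(
                "selected patient=%s k=%d dsc=%.3f", patient.id, k, scores.dsc
            )
    return out


def run_random_arm(
    db: Sequence[PhantomAtlas | AtlasRecord],
    k_values: Iterable[int] = (2, 3, 4, 5, 6, 7, 8),
    limit: int | str = 7,
    seed: int = 0,
    synthetic_config: SyntheticConfig | None = None,
    fusion_config: FusionConfig | None = None,
    registration: Registration | None = None,
    cache: PropagationCache | None = None,
) -> list[RunRecord]:
    """Leave-one-out runs with randomly drawn atlas combinations.

    Per (patient, k), up to ``limit`` distinct random combinations are fused
    and scored (``"all"`` enumerates every combination).  The default limit
    of 7 yields >= 75 runs per k pooled over a 12-patient database.
    """
    records = _records(db)
    k_values = sorted(k_values)
    if len(records) < max(k_values) + 1:
        raise ValueError(
            f"database of {len(records)} atlases too small for k={max(k_values)}"
        )
    fusion_config = fusion_config or FusionConfig()
    if registration is None:
        registration = _default_registration(synthetic_config or SyntheticConfig())
    cache = cache or PropagationCache(registration, seed)

    out: list[RunRecord] = []
    for p_index, patient in enumerate(records):
        pool = [a for a in records if a.id != patient.id]
        by_id = {a.id: a for a in pool}
        for k in k_values:
            combo_seed = int(
                np.random.SeedSequence([seed % (2**31), p_index, k]).generate_state(1)[0]
                % (2**31)
            )
            combos = enumerate_random_combinations(
                [a.id for a in pool], k, limit=limit, seed=combo_seed
            )
            for combo in combos:
                members = [by_id[i] for i in sorted(combo)]
                try:
                    scores = _fuse_and_score(patient, members, cache, fusion_config)
                except Exception as exc:
                    raise RuntimeError(
                        f"random arm failed at patient={patient.id}, k={k}"
                    ) from exc
                out.append(
                    RunRecord(
                        patient_id=patient.id,
                        k=k,
                        strategy="random",
                        combination=combo,
                        scores=scores,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def summarize(records: Sequence[RunRecord]) -> list[GroupSummary]:
    """Per-(strategy, k) mean and sample SD (n-1) of each index.

    Runs are pooled across patients within each (strategy, k) cell.  A
    single-run cell reports SD 0 with ``sd_defined=False``.
    """
    groups: dict[tuple[str, int], list[SimilarityScores]] = {}
    for r in records:
        groups.setdefault((r.strategy, r.k), []).append(r.scores)
    out = []
    for (strategy, k) in sorted(groups, key=lambda g: (g[0], g[1])):
        scores = groups[(strategy, k)]
        arr = np.array([[s.dsc, s.ji, s.ini] for s in scores])
        n = len(scores)
        means = arr.mean(axis=0)
        if n > 1:
            sds = arr.std(axis=0, ddof=1)
            sd_defined = True
        else:
            sds = np.zeros(3)
            sd_defined = False
        out.append(
            GroupSummary(
                strategy=strategy,
                k=k,
                n_runs=n,
                dsc_mean=float(means[0]),
                dsc_sd=float(sds[0]),
                ji_mean=float(means[1]),
                ji_sd=float(sds[1]),
                ini_mean=float(means[2]),
                ini_sd=float(sds[2]),
                sd_defined=sd_defined,
            )
        )
    return out


def _check_group(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"group {name!r} needs n >= 2, got n={arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError(f"group {name!r} contains non-finite values")
    return arr


def independent_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided Welch independent-sample t-test.

    Returns ``(t, p, mean(a) - mean(b))``.  When both groups have zero
    variance and equal means the difference is exactly 0 and p is reported
    as 1 (the no-evidence convention for a degenerate comparison).
    """
    a = _check_group(group_a, "a")
    b = _check_group(group_b, "b")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if diff == 0:
            return 0.0, 1.0, 0.0
        return (math.copysign(math.inf, diff), 0.0, diff)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), diff


def _welch_se_df(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se = math.sqrt(va + vb)
    if va + vb == 0:
        return 0.0, float(a.size + b.size - 2)
    df = (va + vb) ** 2 / (
        va**2 / (a.size - 1) + vb**2 / (b.size - 1)
    )
    return se, df


def equivalence_test(
    reference: Sequence[float],
    comparison: Sequence[float],
    margin_mode: str = "relative",
    margin_value: float = 0.10,
    confidence: float = 0.90,
    reference_k: int = -1,
    comparison_k: int = -1,
) -> EquivalenceResult:
    """Equivalence trial on the difference of two group means.

    Computes d = mean(reference) - mean(comparison) and its two-sided CI at
    the given confidence level using the Welch standard error and t
    quantile (equivalent to two one-sided tests at (1-confidence)/2 each).
    The margin is ``margin_value * mean(reference)`` in relative mode, or
    ``margin_value`` directly in absolute mode.  Equivalence is claimed when
    the whole CI lies within [-margin, +margin].
    """
    a = _check_group(reference, "reference")
    b = _check_group(comparison, "comparison")
    d = float(a.mean() - b.mean())
    se, df = _welch_se_df(a, b)
    if se > 0:
        tq = float(stats.t.ppf(0.5 + confidence / 2.0, df))
        ci_low, ci_high = d - tq * se, d + tq * se
    else:
        ci_low = ci_high = d
    if margin_mode == "relative":
        margin = float(margin_value * a.mean())
    elif margin_mode == "absolute":
        margin = float(margin_value)
    else:
        raise ValueError(f"unknown margin_mode {margin_mode!r}")
    return EquivalenceResult(
        reference_k=reference_k,
        comparison_k=comparison_k,
        mean_difference=d,
        ci_low=ci_low,
        ci_high=ci_high,
        margin=margin,
        equivalent=bool(-margin <= ci_low and ci_high <= margin),
    )


def pick_reference_k(summaries: Sequence[GroupSummary]) -> int:
    """The atlas count with the highest selected-arm mean DSC.

    Ties go to the smaller k (fewer atlases means less computation).
    """
    selected = [s for s in summaries if s.strategy == "selected"]
    if not selected:
        raise ValueError("no selected-arm summaries given")
    best = max(selected, key=lambda s: (s.dsc_mean, -s.k))
    return best.k


def equivalence_ladder(
    records: Sequence[RunRecord],
    reference_k: int | None = None,
    margin_mode: str = "relative",
    margin_value: float = 0.10,
    confidence: float = 0.90,
) -> list[EquivalenceResult]:
    """Equivalence of every other selected-arm k against the reference k.

    Mirrors the clinical question: starting from the best-performing atlas
    count, can the count be increased or decreased without a clinically
    relevant DSC loss?  Uses per-run DSC values pooled across patients.
    """
    selected = [r for r in records if r.strategy == "selected"]
    by_k: dict[int, list[float]] = {}
    for r in selected:
        by_k.setdefault(r.k, []).append(r.scores.dsc)
    if reference_k is None:
        reference_k = pick_reference_k(summarize(selected))
    if reference_k not in by_k:
        raise ValueError(f"reference k={reference_k} not present in records")
    ref = by_k[reference_k]
    out = []
    for k in sorted(by_k):
        if k == reference_k:
            continue
        out.append(
            equivalence_test(
                ref,
                by_k[k],
                margin_mode=margin_mode,
                margin_value=margin_value,
                confidence=confidence,
                reference_k=reference_k,
                comparison_k=k,
            )
        )
    return out


@dataclass
class ExperimentResult:
    """Everything one leave-one-out evaluation produces."""

    selected: list[RunRecord]
    random: list[RunRecord]
    summaries: list[GroupSummary]
    reference_k: int
    t_tests: dict
    equivalence: list[EquivalenceResult]


def run_full_experiment(
    db: Sequence[PhantomAtlas | AtlasRecord],
    synthetic_config: SyntheticConfig | None = None,
    fusion_config: FusionConfig | None = None,
    experiment_config: ExperimentConfig | None = None,
    registration: Registration | None = None,
) -> ExperimentResult:
    """Both arms, summaries, per-k Welch tests and the equivalence ladder.

    Registrations are computed once per (patient, atlas) pair and shared by
    the two arms and all atlas counts.  ``t_tests`` maps each index name to
    per-k ``{"t", "p", "mean_difference"}`` for selected vs random.
    """
    experiment_config = experiment_config or ExperimentConfig()
    fusion_config = fusion_config or FusionConfig()
    if registration is None:
        registration = _default_registration(synthetic_config or SyntheticConfig())
    cache = PropagationCache(registration, experiment_config.seed)

    selected = run_selected_arm(
        db,
        k_values=experiment_config.k_values,
        fusion_config=fusion_config,
        registration=registration,
        seed=experiment_config.seed,
        cache=cache,
    )
    random = run_random_arm(
        db,
        k_values=experiment_config.k_values,
        limit=experiment_config.random_limit,
        seed=experiment_config.seed,
        fusion_config=fusion_config,
        registration=registration,
        cache=cache,
    )
    summaries = summarize(selected + random)
    reference_k = pick_reference_k(summaries)

    t_tests: dict[str, dict[str, dict[str, float]]] = {}
    for index in ("dsc", "ji", "ini"):
        per_k = {}
        for k in sorted(experiment_config.k_values):
            a = [getattr(r.scores, index) for r in selected if r.k == k]
            b = [getattr(r.scores, index) for r in random if r.k == k]
            t, p, d = independent_t_test(a, b)
            per_k[str(k)] = {"t": t, "p": p, "mean_difference": d}
        t_tests[index] = per_k

    ladder = equivalence_ladder(
        selected,
        reference_k=reference_k,
        margin_mode=experiment_config.margin_mode,
        margin_value=experiment_config.margin_value,
        confidence=experiment_config.confidence,
    )
    return ExperimentResult(
        selected=selected,
        random=random,
        summaries=summaries,
        reference_k=reference_k,
        t_tests=t_tests,
        equivalence=ladder,
    )


def sample_size_two_means(
    sd: float, delta: float, power: float = 0.80, alpha: float = 0.10
) -> int:
    """Per-group n for detecting a mean difference ``delta``.

    Standard two-group normal-approximation formula
    ``n = 2 * (z_{1-alpha/2} + z_{power})^2 * sd^2 / delta^2``, rounded up.
    ``alpha`` is two-sided (0.10 corresponds to a 90% CI).
    """
    if delta <= 0:
        raise ValueError(f"detectable difference must be > 0, got {delta}")
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    return int(math.ceil(2.0 * (z_a + z_b) ** 2 * sd**2 / delta**2))
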