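"""Study orchestration: the segmentation sweep, per-subject Bayesian
hyperparameter optimisation, the generalised configuration, and the
statistical comparisons (one-way ANOVA, Tukey HSD).

The synthetic experiments run at desk scale: 5 synthetic subjects,
separability 0.8, a shortened protocol (3 repetitions of 3 s contractions
with 1 s rest), a slimmed CNN (base_filters=6, at most 10 epochs) and
capped per-class training-image counts.  These sizes keep a full sweep-plus-HPO
study within minutes on one CPU while preserving the qualitative structure
of the full-scale experiments; they are settings, not code — every knob is
an argument.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .bayesopt import (
    AcquisitionConfig,
    HyperParams,
    OptimTrace,
    SearchSpace,
    default_search_space,
    run_bayesopt,
)
from .cnn import (
    CNNSpec,
    TrainConfig,
    build_cnn,
    cer_confidence_interval,
    train_cnn,
)
from .exceptions import ConfigError, DataError
from .preprocess import (
    OVERLAP_GRID,
    SEGMENT_SIZE_GRID_MS,
    AugmentationSpec,
    SegmentationSpec,
    SEMGImageSet,
    SplitSpec,
    session_to_images,
)
from .reference import MANUAL_CONFIG
from .synth import (
    GestureProtocol,
    RecordingSession,
    make_subject_model,
    synthesize_session,
)

# ---------------------------------------------------------------------------
# desk-scale study conditions

#: Shortened acquisition schedule used for synthetic experiments.
DESK_PROTOCOL = GestureProtocol(
    n_classes=10, n_reps=3, contraction_s=3.0, rest_s=1.0, fs=200.0, n_channels=8
)
DESK_SEPARABILITY = 0.8
DESK_SENSOR_NOISE = 0.2
DESK_POWERLINE_AMP = 0.2
DESK_N_SUBJECTS = 5

#: Slimmed network/training settings for desk-scale runs.
DESK_BASE_FILTERS = 6
DESK_BATCH_SIZE = 24
DESK_MAX_EPOCHS = 10
DESK_PATIENCE = 2
DESK_TRAIN_CAP_SWEEP = 48  # per class
DESK_TRAIN_CAP_HPO = 24  # per class
DESK_VAL_CAP = 16  # per class

#: The segmentation found optimal in the sweep, reused for the HPO study.
OPTIMAL_SEGMENTATION = SegmentationSpec(mode="overlap", window_ms=200.0, overlap_frac=0.8)


# ---------------------------------------------------------------------------
# results containers


@dataclass
class SubjectResult:
    """Per-subject HPO outcome: best hyperparameters and CERs."""

    subject_id: str
    best_hyperparams: HyperParams
    validation_cer: float
    testing_cer: float
    ci95: tuple[float, float]
    trace: Optional[OptimTrace] = None


@dataclass(frozen=True)
class GeneralizedConfig:
    """Across-subject aggregate: means of the reals, mode of the depth."""

    learning_rate: float
    momentum: float
    l2_strength: float
    section_depth: int

    def to_hyperparams(self) -> HyperParams:
        return HyperParams(
            self.learning_rate, self.momentum, self.l2_strength, self.section_depth
        )


@dataclass
class StudyOutcome:
    """Everything the HPO experiment produces at desk scale."""

    subject_results: list[SubjectResult]
    manual_cers: list[float]
    generalized: GeneralizedConfig
    generalized_cers: list[float]

    @property
    def bayes_mean_test_cer(self) -> float:
        return float(np.mean([r.testing_cer for r in self.subject_results]))

    @property
    def manual_mean_test_cer(self) -> float:
        return float(np.mean(self.manual_cers))

    @property
    def generalized_mean_test_cer(self) -> float:
        return float(np.mean(self.generalized_cers))


# ---------------------------------------------------------------------------
# synthetic subjects


def make_study_sessions(
    n_subjects: int = DESK_N_SUBJECTS,
    separability: float = DESK_SEPARABILITY,
    protocol: GestureProtocol = DESK_PROTOCOL,
    seed: int = 0,
    sensor_noise_rms: float = DESK_SENSOR_NOISE,
    powerline_amp: float = DESK_POWERLINE_AMP,
) -> list[RecordingSession]:
    """Generate one labelled session per synthetic subject."""
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_subjects):
        s_model = int(rng.integers(0, 2**31 - 1))
        s_session = int(rng.integers(0, 2**31 - 1))
        model = make_subject_model(
            protocol,
            separability,
            seed=s_model,
            sensor_noise_rms=sensor_noise_rms,
            powerline_amp=powerline_amp,
        )
        sessions.append(
            synthesize_session(model, protocol, seed=s_session, subject_id=f"S{i + 1:02d}")
        )
    return sessions


def _cap_per_class(imgs: SEMGImageSet, cap: Optional[int]) -> SEMGImageSet:
    if cap is None:
        return imgs
    keep: list[int] = []
    for k in np.unique(imgs.labels):
        idx = np.flatnonzero(imgs.labels == k)[:cap]
        keep.extend(idx.tolist())
    return imgs.subset(np.sort(np.array(keep, dtype=int)))


def _train_and_test(
    images: SEMGImageSet,
    hp: HyperParams,
    seed: int,
    *,
    base_filters: int = DESK_BASE_FILTERS,
    batch_size: int = DESK_BATCH_SIZE,
    max_epochs: int = DESK_MAX_EPOCHS,
    patience: int = DESK_PATIENCE,
    train_cap: Optional[int] = None,
    val_cap: Optional[int] = DESK_VAL_CAP,
    augment: bool = True,
) -> tuple[float, float, int]:
    """Split, cap, train with ``hp`` and return (val CER, test CER, n_test)."""
    train, val, test = split_dataset_cached(images, SplitSpec(seed=seed))
    train = _cap_per_class(train, train_cap)
    val = _cap_per_class(val, val_cap)
    n_classes = int(images.labels.max()) + 1
    spec = CNNSpec(
        section_depth=int(hp.section_depth),
        base_filters=base_filters,
        input_shape=train.images.shape[1:],
        n_classes=n_classes,
    )
    cfg = TrainConfig(
        learning_rate=hp.learning_rate,
        momentum=hp.momentum,
        l2_strength=hp.l2_strength,
        batch_size=batch_size,
        max_epochs=max_epochs,
        early_stop_patience=patience,
        seed=seed,
    )
    aug = (
        AugmentationSpec(flip_prob=0.5, max_shift_px=4, shift_axes="time", seed=seed)
        if augment
        else None
    )
    model = build_cnn(spec, seed=seed)
    trained = train_cnn(model, train, val, cfg, aug)
    return trained.evaluate(val), trained.evaluate(test), len(test)


# caching the split avoids recomputing it for every objective call on the
# same image set; keyed on (id of image set, split seed)
_split_cache: dict = {}


def split_dataset_cached(imgs: SEMGImageSet, spec: SplitSpec):
    from .preprocess import split_dataset

    key = (id(imgs), spec)
    if key not in _split_cache:
        if len(_split_cache) > 64:
            _split_cache.clear()
        _split_cache[key] = split_dataset(imgs, spec)
    return _split_cache[key]


# ---------------------------------------------------------------------------
# experiment 1: segmentation sweep


def segmentation_sweep(
    sessions: Sequence[RecordingSession],
    sizes_ms: Sequence[float] = SEGMENT_SIZE_GRID_MS,
    overlaps: Sequence[float] = OVERLAP_GRID,
    fixed_config: HyperParams = MANUAL_CONFIG,
    seed: int = 0,
    seeds: Optional[Sequence[int]] = None,
    train_cap: Optional[int] = DESK_TRAIN_CAP_SWEEP,
    **train_kwargs,
) -> pd.DataFrame:
    """Test CER per (mode, segment size[, overlap]) condition and subject.

    The identical empirically fixed configuration (depth 3, lr 0.003,
    momentum 0.8383, L2 0.0939) is trained for every condition.  A condition
    that yields zero windows is recorded with a NaN CER and the run
    continues.  Returns one row per condition x subject x seed.
    """
    if not sizes_ms:
        raise ConfigError("sizes_ms must be nonempty")
    if seeds is None:
        seeds = (seed,)
    conditions: list[SegmentationSpec] = []
    for size in sizes_ms:
        conditions.append(SegmentationSpec("disjoint", size))
        for ov in overlaps:
            conditions.append(SegmentationSpec("overlap", size, ov))
    rows = []
    for subject, session in enumerate(sessions):
        for spec in conditions:
            images = session_to_images(session, spec)
            for s in seeds:
                if len(images) == 0:
                    cer = math.nan  # condition yielded no windows; recorded missing
                else:
                    try:
                        _, cer, _ = _train_and_test(
                            images, fixed_config, seed=int(s), train_cap=train_cap,
                            **train_kwargs,
                        )
                    except (DataError, ConfigError):
                        cer = math.nan
                rows.append(
                    {
                        "subject": session.subject_id or f"S{subject + 1:02d}",
                        "mode": spec.mode,
                        "window_ms": spec.window_ms,
                        "overlap_frac": spec.overlap_frac if spec.mode == "overlap" else 0.0,
                        "seed": int(s),
                        "test_cer": cer,
                    }
                )
    return pd.DataFrame(rows)


def mean_cer_across_overlaps(sweep: pd.DataFrame) -> pd.DataFrame:
    """Average overlap-mode CER across the overlap sizes per segment size."""
    out = (
        sweep.groupby(["mode", "window_ms"], as_index=False)["test_cer"]
        .mean()
        .rename(columns={"test_cer": "mean_cer"})
    )
    return out


# ---------------------------------------------------------------------------
# experiment 2: per-subject Bayesian HPO


def optimize_subject(
    session: RecordingSession,
    space: Optional[SearchSpace] = None,
    budget: int = 30,
    cfg: Optional[AcquisitionConfig] = None,
    seed: int = 0,
    segmentation: SegmentationSpec = OPTIMAL_SEGMENTATION,
    train_cap: Optional[int] = DESK_TRAIN_CAP_HPO,
    **train_kwargs,
) -> SubjectResult:
    """Bayesian HPO of one subject with the fixed optimal segmentation.

    The objective is the validation CER of a model trained with the
    candidate hyperparameters; the best candidate is retrained (identical
    seeds, hence identical weights) and reported with its testing CER and
    Wilson 95% interval.
    """
    if space is None:
        space = default_search_space()
    images = session_to_images(session, segmentation)
    if len(images) == 0:
        raise DataError(f"subject {session.subject_id}: no windows to train on")

    def objective(x: dict) -> float:
        hp = HyperParams.from_dict(x)
        val_cer, _, _ = _train_and_test(
            images, hp, seed=seed, train_cap=train_cap, **train_kwargs
        )
        return val_cer

    trace = run_bayesopt(objective, space, budget=budget, cfg=cfg, seed=seed)
    best = HyperParams.from_dict(trace.best_x)
    val_cer, test_cer, n_test = _train_and_test(
        images, best, seed=seed, train_cap=train_cap, **train_kwargs
    )
    return SubjectResult(
        subject_id=session.subject_id,
        best_hyperparams=best,
        validation_cer=trace.best_y,
        testing_cer=test_cer,
        ci95=cer_confidence_interval(test_cer, max(n_test, 1)),
        trace=trace,
    )


def derive_generalized_config(
    results: Sequence[SubjectResult] | Sequence[HyperParams],
) -> GeneralizedConfig:
    """Arithmetic means of the real hyperparameters, mode of the depth.

    Ties in the depth mode break toward the smaller depth (cheaper model).
    """
    if len(results) == 0:
        raise DataError("derive_generalized_config needs at least one result")
    hps = [
        r.best_hyperparams if isinstance(r, SubjectResult) else r for r in results
    ]
    depths = [int(h.section_depth) for h in hps]
    counts = Counter(depths)
    top = max(counts.values())
    mode_depth = min(d for d, c in counts.items() if c == top)
    return GeneralizedConfig(
        learning_rate=float(np.mean([h.learning_rate for h in hps])),
        momentum=float(np.mean([h.momentum for h in hps])),
        l2_strength=float(np.mean([h.l2_strength for h in hps])),
        section_depth=mode_depth,
    )


def run_hpo_study(
    sessions: Optional[Sequence[RecordingSession]] = None,
    budget: int = 30,
    seed: int = 0,
    train_cap: Optional[int] = DESK_TRAIN_CAP_HPO,
    **kwargs,
) -> StudyOutcome:
    """Per-subject Bayesian HPO, manual baseline and generalised config.

    For every subject: run budget-limited Bayesian optimisation, evaluate
    the empirically fixed manual configuration on the same splits, then
    train the generalised configuration derived from all subjects' optima.
    """
    if sessions is None:
        sessions = make_study_sessions(seed=seed)
    results, manual_cers = [], []
    for i, session in enumerate(sessions):
        sub_seed = seed + 1000 * (i + 1)
        res = optimize_subject(
            session, budget=budget, seed=sub_seed, train_cap=train_cap, **kwargs
        )
        results.append(res)
        images = session_to_images(session, OPTIMAL_SEGMENTATION)
        _, manual_test, _ = _train_and_test(
            images, MANUAL_CONFIG, seed=sub_seed, train_cap=train_cap, **kwargs
        )
        manual_cers.append(manual_test)
    generalized = derive_generalized_config(results)
    gen_hp = generalized.to_hyperparams()
    generalized_cers = []
    for i, session in enumerate(sessions):
        sub_seed = seed + 1000 * (i + 1)
        images = session_to_images(session, OPTIMAL_SEGMENTATION)
        _, gen_test, _ = _train_and_test(
            images, gen_hp, seed=sub_seed, train_cap=train_cap, **kwargs
        )
        generalized_cers.append(gen_test)
    return StudyOutcome(results, manual_cers, generalized, generalized_cers)


# ---------------------------------------------------------------------------
# statistics


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: between/within mean-square ratio and p-value."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DataError("one_way_anova needs >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    means = [a.mean() for a in arrays]
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if ssw == 0.0:
        if np.allclose(means, means[0]):
            raise DataError("degenerate ANOVA: zero within-group variance, equal means")
        return math.inf, 0.0
    f, p = spstats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """All-pairs Tukey honest-significant-difference test.

    Returns k(k-1)/2 rows of (group_i, group_j, mean_diff, p_adj) using the
    studentised-range distribution.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DataError("tukey_hsd needs >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = spstats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "mean_diff": float(res.statistic[i, j]),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def summarize_results(
    results: Sequence[SubjectResult] | Sequence[tuple],
) -> pd.DataFrame:
    """Column-wise mean and sample std of the per-subject CER table.

    Accepts :class:`SubjectResult` objects or plain
    ``(validation, testing, ci_low, ci_high)`` tuples.  Values are reported
    to full precision; round to 2 decimals for display.
    """
    if len(results) < 2:
        raise DataError("summarize_results needs >= 2 results")
    if isinstance(results[0], SubjectResult):
        table = pd.DataFrame(
            {
                "validation": [r.validation_cer for r in results],
                "testing": [r.testing_cer for r in results],
                "ci_low": [r.ci95[0] for r in results],
                "ci_high": [r.ci95[1] for r in results],
            }
        )
    else:
        table = pd.DataFrame(
            list(results), columns=["validation", "testing", "ci_low", "ci_high"]
        )
    return pd.DataFrame(
        {"mean": table.mean(axis=0), "std": table.std(axis=0, ddof=1)}
    ).T
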