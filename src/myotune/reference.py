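"""Published per-subject results of the 20-subject Myo-armband gesture study.

These printed per-subject tables are the inputs to the aggregation
utilities: the Bayesian-optimised hyperparameter set found for each subject
(learning rate, SGDM momentum, L2 strength, section depth) and the
corresponding validation/testing classification error rates with their 95%
testing confidence intervals.  They let the generalised-configuration and
summary operations be exercised against real study numbers without the
underlying recordings.
"""

from __future__ import annotations

from .bayesopt import HyperParams

#: Per-subject optimised hyperparameters (subjects 1..20).
SUBJECT_HYPERPARAMS: list[HyperParams] = [
    HyperParams(0.0007, 0.9795, 4.06e-02, 2),
    HyperParams(0.0098, 0.8897, 1.59e-07, 3),
    HyperParams(0.0014, 0.8948, 7.36e-02, 3),
    HyperParams(0.0026, 0.9703, 1.32e-05, 2),
    HyperParams(0.0069, 0.8826, 2.94e-10, 2),
    HyperParams(0.0100, 0.8028, 4.85e-05, 2),
    HyperParams(0.0027, 0.9762, 1.32e-10, 2),
    HyperParams(0.0094, 0.8580, 3.91e-09, 3),
    HyperParams(0.0024, 0.9697, 6.05e-04, 2),
    HyperParams(0.0097, 0.8041, 1.07e-10, 2),
    HyperParams(0.0018, 0.9656, 8.59e-03, 2),
    HyperParams(0.0063, 0.9160, 2.21e-08, 3),
    HyperParams(0.0056, 0.8660, 2.98e-10, 3),
    HyperParams(0.0017, 0.9795, 1.45e-10, 2),
    HyperParams(0.0030, 0.9365, 7.16e-07, 2),
    HyperParams(0.0021, 0.9799, 1.42e-06, 2),
    HyperParams(0.0090, 0.8036, 1.10e-05, 3),
    HyperParams(0.0014, 0.9781, 1.14e-10, 3),
    HyperParams(0.0050, 0.8591, 2.80e-03, 2),
    HyperParams(0.0056, 0.8039, 6.78e-02, 2),
]

#: Per-subject CERs: (validation, testing, ci_low, ci_high), subjects 1..20.
SUBJECT_CERS: list[tuple[float, float, float, float]] = [
    (0.08, 0.10, 0.08, 0.11),
    (0.10, 0.11, 0.09, 0.13),
    (0.09, 0.12, 0.10, 0.14),
    (0.10, 0.12, 0.10, 0.13),
    (0.06, 0.07, 0.05, 0.08),
    (0.08, 0.09, 0.07, 0.11),
    (0.11, 0.12, 0.10, 0.14),
    (0.15, 0.18, 0.16, 0.21),
    (0.08, 0.08, 0.07, 0.10),
    (0.06, 0.06, 0.05, 0.08),
    (0.06, 0.06, 0.04, 0.07),
    (0.08, 0.09, 0.07, 0.11),
    (0.07, 0.07, 0.05, 0.08),
    (0.08, 0.09, 0.07, 0.10),
    (0.03, 0.04, 0.03, 0.05),
    (0.07, 0.08, 0.07, 0.10),
    (0.05, 0.06, 0.04, 0.07),
    (0.03, 0.05, 0.04, 0.06),
    (0.06, 0.08, 0.06, 0.09),
    (0.03, 0.05, 0.03, 0.06),
]

#: Empirically chosen fixed configuration used for the segmentation sweep.
MANUAL_CONFIG = HyperParams(
    learning_rate=0.003, momentum=0.8383, l2_strength=0.0939, section_depth=3
)
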