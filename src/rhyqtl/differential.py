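"""Differential rhythmicity between genotype groups.

Five nested rhythm-sharing models are compared by BIC on the pooled data of
the two largest genotype groups. Every model carries a group-specific mesor,
so a pure expression-level (eQTL) difference can never masquerade as a
differential rhythm; the models differ only in which groups carry harmonic
terms and whether those terms are shared:

====================  =========================================  ==
model                 rhythmic coefficients (a, b)               k
====================  =========================================  ==
M_NONE                absent                                     2
M_A_ONLY              present in group A only                    4
M_B_ONLY              present in group B only                    4
M_SHARED              equal across groups                        4
M_DISTINCT            group-specific                             6
====================  =========================================  ==

BIC = n*ln(RSS/n) + k*ln(n) (Gaussian likelihood; the residual variance is
constant across models and cancels in comparisons). To remove sample-size
bias, the larger group is downsampled without replacement to the smaller
group's size; model selection is repeated over 20 independent downsamples and
a G-test asks whether the selected-model frequencies deviate from a uniform
expectation over the 5 models. A variant-gene pair is called a rhyQTL iff
(1) at least one genotype group is rhythmic (p <= 1e-4, peak-to-trough fold
change >= 1.5), (2) the modal selected model is a differential one, and
(3) the G-test p < 0.05.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import stats

from .io_formats import ExpressionDataset
from .pairing import VariantGenePair, top_two_groups
from .rhythm import (HarmonicFit, NotEstimableError, design_matrix,
                     fit_harmonic, is_rhythmic, phase_difference)


class RhythmModel(IntEnum):
    """The five rhythm-sharing patterns (see module docstring)."""

    M_NONE = 0
    M_A_ONLY = 1
    M_B_ONLY = 2
    M_SHARED = 3
    M_DISTINCT = 4

    @property
    def k(self) -> int:
        return {0: 2, 1: 4, 2: 4, 3: 4, 4: 6}[int(self)]

    @property
    def is_differential(self) -> bool:
        return self in (RhythmModel.M_A_ONLY, RhythmModel.M_B_ONLY, RhythmModel.M_DISTINCT)


MODELS = tuple(RhythmModel)
N_MODELS = len(MODELS)

_MIN_RSS = 1e-300  # floor before the log; interpolating fits tie at -inf otherwise


@dataclass(frozen=True)
class ModelFit:
    model: RhythmModel
    rss: float
    k: int
    bic: float


def fit_model_set(timesA, valuesA, timesB, valuesB) -> dict[RhythmModel, ModelFit]:
    """Fit all five models by least squares on the pooled two-group data."""
    tA = np.asarray(timesA, dtype=float)
    yA = np.asarray(valuesA, dtype=float)
    tB = np.asarray(timesB, dtype=float)
    yB = np.asarray(valuesB, dtype=float)
    nA, nB = len(tA), len(tB)
    if nA < 4 or nB < 4:
        raise NotEstimableError("each group needs n >= 4")
    n = nA + nB
    y = np.concatenate([yA, yB])
    XA = design_matrix(tA)  # [1, cos, sin]
    XB = design_matrix(tB)
    iA = np.concatenate([np.ones(nA), np.zeros(nB)])[:, None]
    iB = 1.0 - iA
    harmA = np.vstack([XA[:, 1:], np.zeros((nB, 2))])
    harmB = np.vstack([np.zeros((nA, 2)), XB[:, 1:]])
    designs = {
        RhythmModel.M_NONE: np.hstack([iA, iB]),
        RhythmModel.M_A_ONLY: np.hstack([iA, iB, harmA]),
        RhythmModel.M_B_ONLY: np.hstack([iA, iB, harmB]),
        RhythmModel.M_SHARED: np.hstack([iA, iB, harmA + harmB]),
        RhythmModel.M_DISTINCT: np.hstack([iA, iB, harmA, harmB]),
    }
    out = {}
    logn = np.log(n)
    for model, X in designs.items():
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise NotEstimableError(f"singular design for {model.name}")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = max(float(resid @ resid), _MIN_RSS)
        bic = n * np.log(rss / n) + model.k * logn
        out[model] = ModelFit(model=model, rss=rss, k=model.k, bic=float(bic))
    return out


def select_model(fits: dict[RhythmModel, ModelFit]) -> RhythmModel:
    """Argmin-BIC model; exact BIC ties resolve to the lowest model id."""
    best = min(fits.values(), key=lambda f: (f.bic, int(f.model)))
    return best.model


def downsample_equal(groupA: np.ndarray, groupB: np.ndarray, rng: np.random.Generator):
    """Downsample the larger group without replacement to the smaller group's size."""
    a = np.asarray(groupA)
    b = np.asarray(groupB)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if len(a) > len(b):
        a = rng.choice(a, size=len(b), replace=False)
    elif len(b) > len(a):
        b = rng.choice(b, size=len(a), replace=False)
    return a, b


def g_test(observed, expected) -> tuple[float, int, float]:
    """Log-likelihood-ratio goodness of fit: G = 2*sum O*ln(O/E), df = C-1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected have different shapes")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be > 0 (pool cells first)")
    if obs.sum() <= 0 or not np.isclose(obs.sum(), exp.sum()):
        raise ValueError("observed and expected totals must match and be > 0")
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    df = len(obs) - 1
    p = float(stats.chi2.sf(g, df))
    return g, df, p


@dataclass
class ModelSelectionResult:
    """Selected models over repeated equal-n downsamples, with the G-test."""

    pair_id: str
    n_repeats: int
    selected: list[RhythmModel]
    freq: np.ndarray  # counts per model id, sums to n_repeats (minus failures)
    g_stat: float
    df: int
    p_g: float
    modal_model: RhythmModel
    n_failed: int = 0

    @property
    def modal_is_differential(self) -> bool:
        return self.modal_model.is_differential


def _pair_seed_key(pair_id: str) -> int:
    return zlib.crc32(pair_id.encode()) & 0x7FFFFFFF


def _modal_model(freq: np.ndarray) -> RhythmModel:
    """Highest-frequency model; ties prefer a differential model, then lowest id."""
    top = freq.max()
    tied = [RhythmModel(i) for i in np.nonzero(freq == top)[0]]
    tied.sort(key=lambda m: (not m.is_differential, int(m)))
    return tied[0]


def repeat_model_selection(
    pair: VariantGenePair,
    dataset: ExpressionDataset,
    n_repeats: int = 20,
    seed: int = 0,
    expected: np.ndarray | None = None,
) -> ModelSelectionResult:
    """Run BIC model selection over ``n_repeats`` equal-n downsamples of a pair.

    Per-repeat seeds derive deterministically from (seed, pair id, repeat), so
    results do not depend on the order pairs are processed in. The G-test
    compares selected-model counts to ``expected`` (default: uniform over the
    five models). Inestimable repeats are excluded and counted.
    """
    dA, dB = top_two_groups(pair)
    times = dataset.times
    values = dataset.values.loc[pair.gene_id].to_numpy(dtype=float)
    idxA, idxB = pair.groups[dA], pair.groups[dB]
    key = _pair_seed_key(pair.pair_id)
    selected: list[RhythmModel] = []
    n_failed = 0
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, key, r]))
        subA, subB = downsample_equal(idxA, idxB, rng)
        try:
            fits = fit_model_set(times[subA], values[subA], times[subB], values[subB])
        except NotEstimableError:
            n_failed += 1
            continue
        selected.append(select_model(fits))
    freq = np.bincount([int(m) for m in selected], minlength=N_MODELS).astype(float)
    n_eff = int(freq.sum())
    if n_eff == 0:
        raise NotEstimableError(f"all {n_repeats} repeats inestimable for {pair.pair_id}")
    exp = np.full(N_MODELS, n_eff / N_MODELS) if expected is None else np.asarray(expected, float)
    g, df, p_g = g_test(freq, exp)
    return ModelSelectionResult(
        pair_id=pair.pair_id, n_repeats=n_repeats, selected=selected,
        freq=freq, g_stat=g, df=df, p_g=p_g,
        modal_model=_modal_model(freq), n_failed=n_failed,
    )


@dataclass
class RhyQTLCall:
    """The three-criterion rhyQTL decision for one variant-gene pair."""

    pair_id: str
    crit1_rhythmic_any_genotype: bool
    crit2_differential_modal: bool
    crit3_gtest: bool
    fits: dict = field(default_factory=dict)  # dosage -> HarmonicFit
    msr: ModelSelectionResult | None = None

    @property
    def is_rhyqtl(self) -> bool:
        return (self.crit1_rhythmic_any_genotype
                and self.crit2_differential_modal
                and self.crit3_gtest)


def call_rhyqtl(
    pair: VariantGenePair,
    fits: dict[int, HarmonicFit],
    msr: ModelSelectionResult,
    p_max: float = 1e-4,
    fc_min: float = 1.5,
    g_p_max: float = 0.05,
) -> RhyQTLCall:
    """Combine per-genotype rhythmicity, modal model class and G-test into a call."""
    crit1 = any(is_rhythmic(f, p_max=p_max, fc_min=fc_min) for f in fits.values())
    return RhyQTLCall(
        pair_id=pair.pair_id,
        crit1_rhythmic_any_genotype=crit1,
        crit2_differential_modal=msr.modal_is_differential,
        crit3_gtest=msr.p_g < g_p_max,
        fits=fits, msr=msr,
    )


def replication_differential(
    fitA: HarmonicFit,
    fitB: HarmonicFit,
    p_max: float = 0.05,
    fc_ratio_min: float = 1.5,
    phase_min_h: float = 3.0,
) -> bool:
    """Two-cohort replication rule for a differential rhythm between genotypes.

    True iff exactly one group is rhythmic at ``p_max``, OR the peak-to-trough
    fold changes differ by more than ``fc_ratio_min``-fold, OR the acrophases
    differ by more than ``phase_min_h`` hours.
    """
    rhyA = fitA.p_value < p_max
    rhyB = fitB.p_value < p_max
    if rhyA != rhyB:
        return True
    fc_hi = max(fitA.fc_ptt, fitB.fc_ptt)
    fc_lo = min(fitA.fc_ptt, fitB.fc_ptt)
    if fc_hi / fc_lo > fc_ratio_min:
        return True
    return phase_difference(fitA.phase, fitB.phase) > phase_min_h
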