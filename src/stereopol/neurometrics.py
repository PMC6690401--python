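"""Neuron/anti-neuron front/back task and efficiency ratios.

The simulated observer sees one noisy stereogram per trial, always at the
positive stimulus disparity, and answers from a fixed decision pair: correct
when the model neuron tuned to +disparity responds more strongly than the
"anti-neuron" tuned to -disparity (ties broken by a fair coin; they occur
with the rectified RPC models, where both responses can be exactly zero).

Statistical efficiency between two conditions is the squared ratio of
probit-transformed proportions correct, i.e. the squared sensitivity ratio
of the two observers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .energymodel import (
    GaborParams,
    NeuronModel,
    neuron_response,
    binocular_profiles,
)
from .stimgen import (
    PolarityMode,
    StimulusParams,
    generate_pair,
    generate_uncorrelated_pair,
    normalize,
    to_same_polarity,
)

#: spawn key reserved for the tie-breaking stream (pair streams use small keys)
_TIE_STREAM_KEY = 1 << 20


@dataclass(frozen=True)
class TaskResult:
    condition: PolarityMode
    n_trials: int
    pc: float  # proportion correct, in [0, 1]
    model: NeuronModel
    seed: int

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.pc

    @property
    def se_pc(self) -> float:
        """Binomial standard error of the proportion correct."""
        return float(np.sqrt(self.pc * (1.0 - self.pc) / self.n_trials))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "model": self.model.value,
            "n_trials": self.n_trials,
            "pc": self.pc,
            "percent_correct": self.percent_correct,
            "seed": self.seed,
        }


def efficiency_ratio(pc_a: float, pc_b: float) -> float:
    """Squared ratio of probit-transformed proportions correct,
    (probit(pc_a) / probit(pc_b))^2: the factor by which observer A uses
    stimulus information more efficiently than observer B."""
    for name, pc in (("pc_a", pc_a), ("pc_b", pc_b)):
        if not 0.5 < pc < 1.0:
            raise ValueError(
                f"{name} must lie strictly between 0.5 and 1 "
                f"(got {pc}); the efficiency ratio is undefined otherwise"
            )
    return float((ndtri(pc_a) / ndtri(pc_b)) ** 2)


def _decide(r_pref: np.ndarray, r_anti: np.ndarray, rng: np.random.Generator):
    """Correct/incorrect per trial, fair coin on exact ties."""
    correct = r_pref > r_anti
    ties = r_pref == r_anti
    if np.any(ties):
        correct = correct | (ties & (rng.random(np.shape(ties)) < 0.5))
    return correct


def run_conditions(
    stim_params: StimulusParams,
    models: Sequence[NeuronModel],
    disparity_px: int,
    n_trials: int,
    seed: Optional[int] = None,
    gabor: GaborParams = GaborParams(),
    conditions: Sequence[PolarityMode] = (PolarityMode.MIXED, PolarityMode.BLACK),
    uncorrelated: bool = False,
) -> Dict[Tuple[NeuronModel, PolarityMode], TaskResult]:
    """Front/back task for several models and polarity conditions at once.

    One mixed-polarity stereogram ensemble (at +disparity) is generated and
    each same-polarity condition is derived from the identical dot patterns,
    so conditions differ only in dot polarity, never in layout.
    """
    if n_trials < 100:
        warnings.warn(
            "n_trials < 100: the binomial SE of percent correct is too large "
            "for meaningful condition comparisons",
            stacklevel=2,
        )
    if seed is None:
        seed = stim_params.seed
    params = replace(
        stim_params,
        mean_disparity_px=disparity_px,
        polarity_mode=PolarityMode.MIXED,
        seed=seed,
    )
    tie_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_TIE_STREAM_KEY,))
    )
    models = list(models)
    conditions = list(conditions)
    x0 = [disparity_px, -disparity_px]

    resp = {
        (m, c): np.empty((n_trials, 2)) for m in models for c in conditions
    }
    for t in range(n_trials):
        mixed = (
            generate_uncorrelated_pair(params, pair_index=t)
            if uncorrelated
            else generate_pair(params, pair_index=t)
        )
        for cond in conditions:
            pair = mixed if cond is PolarityMode.MIXED else to_same_polarity(mixed, cond)
            pair = normalize(pair)
            v = binocular_profiles(pair.left, pair.right, x0, gabor)
            for m in models:
                resp[(m, cond)][t] = neuron_response(
                    v["v_le"], v["v_re"], v["v_lo"], v["v_ro"], m
                )

    out = {}
    for (m, cond), r in resp.items():
        correct = _decide(r[:, 0], r[:, 1], tie_rng)
        out[(m, cond)] = TaskResult(
            condition=cond if cond is PolarityMode.MIXED else cond,
            n_trials=n_trials,
            pc=float(np.mean(correct)),
            model=m,
            seed=seed,
        )
    return out


def run_task(
    stim_params: StimulusParams,
    model: NeuronModel,
    disparity_px: int,
    n_trials: int,
    seed: Optional[int] = None,
    gabor: GaborParams = GaborParams(),
    uncorrelated: bool = False,
) -> TaskResult:
    """Front/back task for a single model under the polarity condition given
    by ``stim_params.polarity_mode``."""
    cond = stim_params.polarity_mode
    res = run_conditions(
        stim_params,
        [model],
        disparity_px,
        n_trials,
        seed=seed,
        gabor=gabor,
        conditions=[cond],
        uncorrelated=uncorrelated,
    )
    return res[(model, cond)]


def results_to_dataframe(results) -> pd.DataFrame:
    rows = [r.to_dict() for r in (results.values() if isinstance(results, dict) else results)]
    return pd.DataFrame(rows)
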