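"""Score candidate structural models against measured biophysical data.

Each model's predicted transport/spectroscopic quantities are compared
with the observations; a property is "consistent" when the absolute
deviation is within its stated tolerance, and models are ranked by the
total tolerance-scaled deviation.  This is the inference step that
selects among competing folds of a promoter sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Observation",
    "ModelComparison",
    "compare",
    "mutant_shift_report",
    "DEFAULT_TOLERANCES",
]

# default agreement tolerances per property: the stated model uncertainty
# for s20w (+/- 0.1 S) and the measurement error for rho (+/- 4.1 ns)
DEFAULT_TOLERANCES = {"s20w": 0.1, "rho_ns": 4.1, "cd_amplitude_ratio": 0.5}


@dataclass
class Observation:
    value: float
    uncertainty: float = 0.0


@dataclass
class ModelComparison:
    model_id: str
    predicted: dict
    deviations: dict = field(default_factory=dict)   # property -> |pred-obs|
    verdicts: dict = field(default_factory=dict)     # property -> bool
    score: float = 0.0

    @property
    def consistent(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


def compare(models: list[tuple[str, dict]],
            observed: dict[str, Observation | tuple | float],
            tolerances: dict | None = None,
            metric: str = "linear") -> list[ModelComparison]:
    """Rank candidate models by agreement with observations.

    ``models`` is a list of (model_id, {property: predicted value});
    ``observed`` maps property names to :class:`Observation` (or plain
    value / (value, uncertainty) tuples).  Properties a model does not
    predict are skipped with a warning, never imputed.  Score is the sum
    of |pred - obs| / tolerance over scored properties (``metric =
    "chi2"`` squares the terms); ties rank by model_id.
    """
    if not models:
        raise ValueError("need at least one model")
    if not observed:
        raise ValueError("need at least one observed property")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    obs: dict[str, Observation] = {}
    for key, val in observed.items():
        if isinstance(val, Observation):
            obs[key] = val
        elif isinstance(val, (tuple, list)):
            obs[key] = Observation(*val)
        else:
            obs[key] = Observation(float(val))

    results = []
    for model_id, predicted in models:
        cmp = ModelComparison(model_id=model_id, predicted=dict(predicted))
        for prop, ob in obs.items():
            if prop not in predicted:
                warnings.warn(f"model '{model_id}' predicts no '{prop}'; "
                              "property skipped")
                continue
            t = tol.get(prop)
            if t is None or t <= 0:
                raise ValueError(f"no positive tolerance for '{prop}'")
            dev = abs(predicted[prop] - ob.value)
            cmp.deviations[prop] = dev
            cmp.verdicts[prop] = dev <= t
            term = dev / t
            cmp.score += term * term if metric == "chi2" else term
        results.append(cmp)
    results.sort(key=lambda c: (c.score, c.model_id))
    return results


def mutant_shift_report(wt_s20w: float, mutant_s20w: list[float],
                        sigma: float = 0.04) -> dict:
    """Direction and magnitude of mutant sedimentation shifts vs wild type.

    A mutant is classified ``expanded`` when its s drops by more than
    2*sigma (slower sedimentation at fixed mass means a larger frictional
    envelope), ``compacted`` for the opposite shift, else ``unchanged``.
    """
    if wt_s20w <= 0 or any(s <= 0 for s in mutant_s20w):
        raise ValueError("sedimentation coefficients must be positive")
    entries = []
    for s in mutant_s20w:
        delta = s - wt_s20w
        if delta < -2.0 * sigma:
            label = "expanded"
        elif delta > 2.0 * sigma:
            label = "compacted"
        else:
            label = "unchanged"
        entries.append({"s20w": s, "delta_s": delta, "classification": label})
    deltas = [e["delta_s"] for e in entries]
    return {"wt_s20w": wt_s20w, "mutants": entries,
            "mean_delta_s": sum(deltas) / len(deltas) if deltas else 0.0,
            "sigma": sigma}
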