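"""Rule-based diagnosis of the nine balance-pair scenarios.

Two flow balances determine the status of a polyphosphate-accumulating
population in an anaerobic/aerobic enrichment cycle:

* carbon vs electron flow in the AN phase — state A (balanced),
  B (primary carbon source in excess of the primary electron source) or
  C (primary carbon source insufficient);
* electron vs energy flow across the cycle — state 1 (balanced),
  2 (phosphorus overloading: extra AE-phase electron flow into ETP funds
  additional P uptake) or 3 (phosphorus limitation: the PolyP module and
  the P transporters fall silent and glycogen is over-replenished).

Their product gives nine scenarios A1..C3.  A1 is optimal; A2, C1 and C2
still favour enrichment of the target population, while every B scenario
(unconsumed acetate feeding competitors) and every *3 scenario (phosphorus
starvation pushing the population toward glycogen-accumulating behaviour)
are unfavourable.

Module activities are turned into qualitative levels by z-scoring each
module against all modules of the same phase (high: z > +0.5, low:
z < -0.5 by default).  The across-module spread is floored at ``min_sd``
LCRPKM units so that a phase with no real signal (near-zero variance)
yields all-baseline levels instead of amplifying noise.  Each axis state
is then a vote count over the diagnostic modules; a state is called only
when its score beats the opposing score by more than ``margin`` votes,
with ties resolved to the balanced state (the conservative,
no-intervention call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .transcription import ActivityProfile

__all__ = [
    "DiagnosisConfig",
    "ScenarioDiagnosis",
    "module_level",
    "module_levels",
    "carbon_electron_state",
    "electron_energy_state",
    "diagnose",
    "FAVORABLE_SCENARIOS",
]

Level = Literal["high", "baseline", "low", "unknown"]

FAVORABLE_SCENARIOS = frozenset({"A1", "A2", "C1", "C2"})

#: modules consulted by each axis
CARBON_RULE_MODULES = (3, 4, 5, 7, 9, 10, 11, 12)
ENERGY_RULE_MODULES = (6, 7, 10, 13, 14, 15)


@dataclass(frozen=True)
class DiagnosisConfig:
    """Thresholds of the qualitative rule table."""

    z_high: float = 0.5
    z_low: float = -0.5
    margin: int = 1          # votes by which one state must beat the other
    min_sd: float = 0.3      # LCRPKM units; floor on the across-module SD


@dataclass
class ScenarioDiagnosis:
    """Scenario call with its evidence and enrichment recommendation."""

    carbon_state: str        # A | B | C | indeterminate
    phosphorus_state: str    # 1 | 2 | 3 | indeterminate
    scenario: str
    favorable: bool
    recommendation: str
    evidence: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Balance-pair diagnosis",
            "=" * 40,
            f"carbon vs electron (AN):   state {self.carbon_state}",
            f"electron vs energy:        state {self.phosphorus_state}",
            f"scenario:                  {self.scenario}",
            f"favorable for enrichment:  {'yes' if self.favorable else 'no'}",
            f"recommendation:            {self.recommendation}",
            "",
            "votes:",
        ]
        for axis in ("carbon", "phosphorus"):
            scores = self.evidence.get(axis, {}).get("scores", {})
            hits = self.evidence.get(axis, {}).get("hits", {})
            for state, score in scores.items():
                lines.append(f"  {axis} {state}: {score}  {hits.get(state, [])}")
        return "\n".join(lines)


def module_levels(
    ap: ActivityProfile, phase: str, config: DiagnosisConfig = DiagnosisConfig()
) -> dict[int, Level]:
    """Qualitative level of every module in a phase, by floored z-score."""
    vals = ap.phase_values(phase)
    if not vals:
        return {}
    arr = np.array(list(vals.values()), dtype=float)
    mean = float(arr.mean())
    sd = max(float(arr.std(ddof=0)), config.min_sd)
    out: dict[int, Level] = {}
    for mid, v in vals.items():
        z = (v - mean) / sd
        if z > config.z_high:
            out[mid] = "high"
        elif z < config.z_low:
            out[mid] = "low"
        else:
            out[mid] = "baseline"
    return out


def module_level(
    ap: ActivityProfile,
    module_id: int,
    phase: str,
    config: DiagnosisConfig = DiagnosisConfig(),
) -> Level:
    """Level of one module in one phase; "unknown" when it has no activity."""
    levels = module_levels(ap, phase, config)
    return levels.get(module_id, "unknown")


def _vote(levels: Mapping[int, Level], rules: list[tuple[int, Level, str]]):
    """Count satisfied rules; each rule is (module, wanted level, tag)."""
    score = 0
    hits: list[str] = []
    for mid, wanted, tag in rules:
        if levels.get(mid, "unknown") == wanted:
            score += 1
            hits.append(tag)
    return score, hits


def _decide(
    score_a: int, score_b: int, label_a: str, label_b: str,
    balanced: str, margin: int,
) -> str:
    if score_a - score_b > margin:
        return label_a
    if score_b - score_a > margin:
        return label_b
    return balanced


def carbon_electron_state(
    levels_an: Mapping[int, Level], config: DiagnosisConfig = DiagnosisConfig()
) -> tuple[str, dict]:
    """AN-phase carbon-vs-electron balance: A, B, C or indeterminate.

    B evidence (carbon excess): the complete and partial TCA cycles run in
    the AN phase to burn surplus acetate into extra electrons while the
    oxidative split-TCA branch idles — with no recruitment of secondary
    carbon sources.  C evidence (carbon insufficiency): secondary carbon
    modules (LCFA, AA, glutamate) are recruited and surplus electrons are
    dumped through denitrification, hydrogenases and the oxidative branch.
    """
    known = sum(1 for m in CARBON_RULE_MODULES if m in levels_an)
    if known < len(CARBON_RULE_MODULES) / 2:
        return "indeterminate", {
            "warning": "more than half of the carbon-rule modules are unknown",
            "scores": {}, "hits": {},
        }
    b_score, b_hits = _vote(levels_an, [
        (7, "high", "complete TCA high (AN)"),
        (10, "high", "partial TCA high (AN)"),
        (9, "low", "oxidative split-TCA branch low (AN)"),
    ])
    c_score, c_hits = _vote(levels_an, [
        (3, "high", "LCFA high (AN)"),
        (4, "high", "AA high (AN)"),
        (5, "high", "glutamate/N high (AN)"),
        (9, "high", "oxidative split-TCA branch high (AN)"),
        (11, "high", "denitrification high (AN)"),
        (12, "high", "hydrogenases high (AN)"),
    ])
    state = _decide(b_score, c_score, "B", "C", "A", config.margin)
    evidence = {
        "scores": {"B": b_score, "C": c_score},
        "hits": {"B": b_hits, "C": c_hits},
        "secondary_carbon_not_high": all(
            levels_an.get(m) != "high" for m in (3, 4, 5)
        ),
    }
    return state, evidence


def electron_energy_state(
    levels_an: Mapping[int, Level],
    levels_ae: Mapping[int, Level],
    config: DiagnosisConfig = DiagnosisConfig(),
) -> tuple[str, dict]:
    """Electron-vs-energy balance: 1, 2, 3 or indeterminate.

    State 2 (P overloading): complete TCA and ETP run high in the AE phase
    and the PolyP module and P transporters are strongly expressed.  State
    3 (P limitation): PolyP and the transporters are low while glycogen
    replenishment (partial TCA into Gly) and AN-phase ETP compensate for
    the missing PolyP energy.  PolyP and transporter levels are read in
    the AE phase, where polyphosphate is recharged.
    """
    known = sum(
        1 for m in ENERGY_RULE_MODULES if m in levels_an or m in levels_ae
    )
    if known < len(ENERGY_RULE_MODULES) / 2:
        return "indeterminate", {
            "warning": "more than half of the energy-rule modules are unknown",
            "scores": {}, "hits": {},
        }
    two_score, two_hits = _vote(levels_ae, [
        (7, "high", "complete TCA high (AE)"),
        (15, "high", "ETP high (AE)"),
        (13, "high", "PolyP high (AE)"),
        (14, "high", "P transporters high (AE)"),
    ])
    three_score, three_hits = _vote(levels_ae, [
        (13, "low", "PolyP low (AE)"),
        (14, "low", "P transporters low (AE)"),
        (6, "high", "Gly high (AE)"),
        (10, "high", "partial TCA high (AE)"),
    ])
    s, h = _vote(levels_an, [(15, "high", "ETP high (AN)")])
    three_score += s
    three_hits += h
    state = _decide(two_score, three_score, "2", "3", "1", config.margin)
    evidence = {
        "scores": {"2": two_score, "3": three_score},
        "hits": {"2": two_hits, "3": three_hits},
    }
    return state, evidence


_RECOMMENDATIONS = {
    "B": ("reduce the carbon (acetate) feeding: unconsumed acetate promotes "
          "the growth of competing organisms"),
    "3": ("increase the phosphorus supply: phosphorus limitation pushes the "
          "population toward glycogen-accumulating behaviour"),
}


def diagnose(
    ap: ActivityProfile, config: DiagnosisConfig = DiagnosisConfig()
) -> ScenarioDiagnosis:
    """Classify an activity profile into one of the nine scenarios."""
    levels_an = module_levels(ap, "AN", config)
    levels_ae = module_levels(ap, "AE", config)
    carbon, carbon_ev = carbon_electron_state(levels_an, config)
    phosphorus, p_ev = electron_energy_state(levels_an, levels_ae, config)

    scenario = f"{carbon if carbon != 'indeterminate' else '?'}" \
               f"{phosphorus if phosphorus != 'indeterminate' else '?'}"
    favorable = scenario in FAVORABLE_SCENARIOS

    recs = []
    if carbon == "B":
        recs.append(_RECOMMENDATIONS["B"])
    if phosphorus == "3":
        recs.append(_RECOMMENDATIONS["3"])
    if "indeterminate" in (carbon, phosphorus):
        recs.append("resolve the indeterminate axis before intervening")
    if not recs:
        recs.append("maintain current feeding; conditions favour enrichment"
                    if favorable else "maintain current feeding")
    return ScenarioDiagnosis(
        carbon_state=carbon,
        phosphorus_state=phosphorus,
        scenario=scenario,
        favorable=favorable,
        recommendation="; ".join(recs),
        evidence={
            "carbon": carbon_ev,
            "phosphorus": p_ev,
            "levels": {"AN": levels_an, "AE": levels_ae},
        },
    )
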