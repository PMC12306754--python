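"""Assemble a simplified per-limb decision-support report: the 12-surgery
recommendation profile, per-surgery Shapley indication tables, and
outcome-prediction displays with 50%/90% intervals for the treated,
control and effect arms.  Rendered as JSON plus a plain-text document;
colors follow the two-hue convention (green = indication/treated,
purple = counter-indication/untreated)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from .explain import indication_table, shapley_values
from .propensity import recommendation_profile

GREEN, PURPLE = "green", "purple"


@dataclass
class EBReport:
    limb_id: str
    profile: list                      # RecommendationRow per surgery
    shapley_tables: dict[str, pd.DataFrame]
    effect_displays: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "limb_id": self.limb_id,
            "profile": [{
                "treatment": r.treatment, "probability": r.probability,
                "interval_90": list(r.interval_90), "category": r.category,
                "color": GREEN if r.category >= 4 else (
                    PURPLE if r.category <= 2 else "neutral"),
            } for r in self.profile],
            "shapley": {k: v.to_dict(orient="records")
                        for k, v in self.shapley_tables.items()},
            "effects": {k: v.to_dict(orient="index")
                        for k, v in self.effect_displays.items()},
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, default=float)

    def to_text(self) -> str:
        lines = [f"EB report for {self.limb_id}",
                 "=" * 40, "", "Treatment recommendation profile:"]
        for r in sorted(self.profile, key=lambda r: -r.probability):
            lines.append("  " + r.label)
        for name, table in self.shapley_tables.items():
            lines += ["", f"Indications for {name} "
                          "(positive = indication, negative = counter-indication):"]
            for _, row in table.iterrows():
                lines.append(f"  {row['feature']:<28s} {row['shapley']:+.3f} "
                             f"[{row['strength']}, {row['source']}]")
        for name, disp in self.effect_displays.items():
            lines += ["", f"Predicted change in {name}:"]
            for arm, row in disp.iterrows():
                lines.append(
                    f"  {arm:<8s} mean {row['mean']:+6.1f}  "
                    f"50% [{row['lo50']:+6.1f}, {row['hi50']:+6.1f}]  "
                    f"90% [{row['lo90']:+6.1f}, {row['hi90']:+6.1f}]")
        return "\n".join(lines)


def build_report(limb: pd.DataFrame, propensity_fits: dict,
                 outcome_fits: dict, *, explain_treatments=None,
                 effect_treatments=None, seed: int = 0) -> EBReport:
    """Build the report for a single limb row.

    ``explain_treatments`` selects which surgeries get Shapley tables
    (default: those with mean probability above 0.5); ``effect_treatments``
    the treatment set for the outcome displays (default: the same).
    """
    if len(limb) != 1:
        raise ValueError("limb must be a single-row DataFrame")
    limb_id = str(limb.index[0])
    profile = recommendation_profile(propensity_fits, limb)
    if explain_treatments is None:
        explain_treatments = [r.treatment for r in profile if r.probability > 0.5]
    shapley_tables = {
        t: indication_table(shapley_values(propensity_fits[t], limb, seed=seed))
        for t in explain_treatments}
    if effect_treatments is None:
        effect_treatments = explain_treatments
    effect_displays = {}
    if effect_treatments:
        for name, ofit in outcome_fits.items():
            est = ofit.estimate_treatment_effect(limb, tuple(effect_treatments))
            effect_displays[name] = est.summary_frame()
    meta = {"generated": datetime.now(timezone.utc).isoformat(),
            "seed": seed,
            "propensity_seeds": {t: f.seed for t, f in propensity_fits.items()},
            "outcome_seeds": {n: f.seed for n, f in outcome_fits.items()}}
    return EBReport(limb_id, profile, shapley_tables, effect_displays, meta)
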