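"""Drug-combination synergy calls from fractional responses.

Given the fractional response to drug A alone (Fa), drug B alone (Fb) and
the combination (Fc), the default criterion declares synergy when
Fc > Fa * (1 - Fb) — implemented literally as stated by its source, and
kept distinct from classic Bliss independence, whose expected combination
response is Fa + Fb - Fa * Fb. Both reference models are exposed; which
one is appropriate depends on whether "fractional response" is read as
fraction affected or fraction surviving (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ValidationError

__all__ = [
    "ComboResponse",
    "expected_combination",
    "is_synergistic",
    "evaluate_combos",
]

MODES = ("literal", "bliss")


@dataclass(frozen=True)
class ComboResponse:
    """Fractional responses for one drug combination, each in [0, 1]."""

    fa: float
    fb: float
    fc: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("fa", "fb", "fc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


def expected_combination(fa: float, fb: float, mode: str = "literal") -> float:
    """Reference combination response: Fa*(1-Fb) ('literal') or Bliss."""
    if not (0.0 <= fa <= 1.0 and 0.0 <= fb <= 1.0):
        raise ValidationError("fractional responses must lie in [0, 1]")
    if mode == "literal":
        return fa * (1.0 - fb)
    if mode == "bliss":
        return fa + fb - fa * fb
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def is_synergistic(r: ComboResponse, mode: str = "literal") -> tuple[bool, float]:
    """Strict-inequality synergy call plus the margin fc - threshold."""
    threshold = expected_combination(r.fa, r.fb, mode=mode)
    margin = r.fc - threshold
    return margin > 0.0, margin


def evaluate_combos(table: pd.DataFrame, mode: str = "literal") -> pd.DataFrame:
    """Apply the synergy criterion to a table with columns label, fa, fb, fc."""
    required = {"fa", "fb", "fc"}
    if not required.issubset(table.columns):
        raise ValidationError(f"combo table needs columns {sorted(required)}")
    rows = []
    for _, row in table.iterrows():
        combo = ComboResponse(
            fa=float(row["fa"]),
            fb=float(row["fb"]),
            fc=float(row["fc"]),
            label=str(row.get("label", "")),
        )
        syn, margin = is_synergistic(combo, mode=mode)
        rows.append(
            {
                "label": combo.label,
                "fa": combo.fa,
                "fb": combo.fb,
                "fc": combo.fc,
                "threshold": expected_combination(combo.fa, combo.fb, mode=mode),
                "margin": margin,
                "synergistic": syn,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "fa", "fb", "fc", "threshold", "margin", "synergistic"],
    )
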