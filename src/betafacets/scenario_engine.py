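"""Construction of the four compositional scenarios.

The historical matrix holds pre-disturbance native composition; the current
matrix holds extant natives (minus any globally extinct species) plus the
naturalised exotics.  Two hypothetical futures intensify extinction by
conservation status: future-1 removes natives currently classed Endangered,
future-2 removes Endangered and Vulnerable natives.  Exotic composition is
held fixed across current and both futures.

Status-driven removal acts at the species level (a removed species loses all
of its basin presences): the scenario definitions count whole species, which
is only consistent with species-level application.  Per-basin status tables
can be emulated by pre-splitting a species into basin-specific rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import (
    OccurrenceMatrix,
    Origin,
    ScenarioSet,
    SpeciesRecord,
    Status,
    ValidationError,
)

_REMOVABLE = {Status.CR, Status.EN, Status.VU, Status.NT, Status.LC}


@dataclass(frozen=True)
class ExtinctionRule:
    """Which conservation statuses go extinct; only natives are eligible."""

    statuses_removed: frozenset[Status]

    def __post_init__(self) -> None:
        bad = set(self.statuses_removed) - _REMOVABLE
        if bad:
            raise ValidationError(
                f"statuses not eligible for simulated extinction: "
                f"{sorted(s.value for s in bad)}"
            )


FUTURE1_RULE = ExtinctionRule(frozenset({Status.EN}))
FUTURE2_RULE = ExtinctionRule(frozenset({Status.EN, Status.VU}))


def apply_extinctions(
    occ: OccurrenceMatrix,
    meta: list[SpeciesRecord],
    rule: ExtinctionRule,
    scenario: str,
) -> OccurrenceMatrix:
    """Zero the rows of native species whose status falls under the rule.

    Exotic species are never removed.  The result carries the target
    scenario label; all other rows are unchanged.
    """
    by_id = {r.species_id: r for r in meta}
    missing = [s for s in occ.species if s not in by_id]
    if missing:
        raise ValidationError(f"species missing from metadata: {missing[:5]}")
    out = occ.copy(scenario=scenario)
    for i, sid in enumerate(occ.species):
        rec = by_id[sid]
        if rec.origin is Origin.NATIVE and rec.status in rule.statuses_removed:
            out.values[i, :] = 0
    return out


def build_scenarios(
    historical: OccurrenceMatrix,
    current: OccurrenceMatrix,
    meta: list[SpeciesRecord],
    future1_rule: ExtinctionRule = FUTURE1_RULE,
    future2_rule: ExtinctionRule = FUTURE2_RULE,
) -> ScenarioSet:
    """Assemble the four aligned scenario matrices.

    Futures are derived from the current matrix by the two extinction rules.
    Species flagged extinct in the metadata must already be absent from the
    current matrix (they exist only historically); a violation is an error.
    """
    if historical.basins != current.basins or historical.species != current.species:
        raise ValidationError("historical and current matrices are misaligned")
    by_id = {r.species_id: r for r in meta}
    missing = [s for s in current.species if s not in by_id]
    if missing:
        raise ValidationError(f"species missing from metadata: {missing[:5]}")
    for i, sid in enumerate(current.species):
        if by_id[sid].extinct and current.values[i].any():
            raise ValidationError(
                f"species {sid!r} is flagged extinct but present in the "
                f"current matrix"
            )
    future1 = apply_extinctions(current, meta, future1_rule, "future1")
    future2 = apply_extinctions(current, meta, future2_rule, "future2")
    return ScenarioSet(
        {
            "historical": historical.copy(scenario="historical"),
            "current": current.copy(scenario="current"),
            "future1": future1,
            "future2": future2,
        }
    )
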