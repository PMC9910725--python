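"""Reading, writing and validation of the three input tables.

The canonical on-disk format for every table is plain CSV (UTF-8, comma
separated, one header row, first column ``species_id``).  A converter ingests
the "bracket" dialect used by published occurrence compilations, in which a
single cell encodes presence under four compositional scenarios as
``[historical, current, future1, future2]`` and the token ``1/0`` marks a
species extirpated after the historical period.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SCENARIOS = ("historical", "current", "future1", "future2")


class ValidationError(ValueError):
    """An input table violates the format contract."""


class Origin(str, enum.Enum):
    NATIVE = "native"
    EXOTIC = "exotic"


class Status(str, enum.Enum):
    """Conservation status; NE = not evaluated (all exotics)."""

    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"
    NE = "NE"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' identity, origin, conservation status and extinction flag."""

    species_id: str
    origin: Origin
    status: Status
    extinct: bool = False

    def __post_init__(self) -> None:
        if self.origin is Origin.EXOTIC and self.status is not Status.NE:
            raise ValidationError(
                f"exotic species {self.species_id!r} must have status NE, "
                f"got {self.status.value}"
            )


@dataclass
class OccurrenceMatrix:
    """Binary species x basins matrix labelled with a compositional scenario."""

    scenario: str
    basins: list[str]
    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.values.shape != (len(self.species), len(self.basins)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.species)} species x {len(self.basins)} basins"
            )
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at species {self.species[bad[0]]!r}, "
                f"basin {self.basins[bad[1]]!r}"
            )
        for kind, labels in (("species", self.species), ("basin", self.basins)):
            dupes = {x for x in labels if labels.count(x) > 1}
            if dupes:
                raise ValidationError(f"duplicated {kind} label(s): {sorted(dupes)}")
        self.values = self.values.astype(np.uint8)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_basins(self) -> int:
        return len(self.basins)

    def richness(self) -> np.ndarray:
        """Species count per basin (column sums)."""
        return self.values.sum(axis=0).astype(int)

    def species_index(self, species_id: str) -> int:
        return self.species.index(species_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.species, name="species_id"),
                            columns=self.basins)

    def copy(self, scenario: str | None = None) -> "OccurrenceMatrix":
        return OccurrenceMatrix(
            scenario=scenario or self.scenario,
            basins=list(self.basins),
            species=list(self.species),
            values=self.values.copy(),
        )


@dataclass
class ScenarioSet:
    """One OccurrenceMatrix per compositional scenario, sharing basin and
    species order."""

    matrices: dict[str, OccurrenceMatrix]

    def __post_init__(self) -> None:
        missing = set(SCENARIOS) - set(self.matrices)
        if missing:
            raise ValidationError(f"missing scenario matrices: {sorted(missing)}")
        ref = self.matrices[SCENARIOS[0]]
        for name in SCENARIOS[1:]:
            m = self.matrices[name]
            if m.basins != ref.basins:
                raise ValidationError(f"scenario {name!r} basin list differs")
            if m.species != ref.species:
                raise ValidationError(f"scenario {name!r} species list differs")

    def __getitem__(self, scenario: str) -> OccurrenceMatrix:
        return self.matrices[scenario]

    @property
    def basins(self) -> list[str]:
        return self.matrices["historical"].basins

    @property
    def species(self) -> list[str]:
        return self.matrices["historical"].species


# ---------------------------------------------------------------------------
# species metadata

_REQUIRED_META_COLUMNS = ("species_id", "origin", "status")
_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no", ""}


def read_species_metadata(path: str | Path) -> list[SpeciesRecord]:
    """Read the species metadata CSV into a list of :class:`SpeciesRecord`.

    Required columns: ``species_id``, ``origin``, ``status``; optional
    ``extinct`` (0/1 or true/false, default false).  Unknown origin or status
    tokens raise :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    records: list[SpeciesRecord] = []
    for i, row in df.iterrows():
        sid = row["species_id"].strip()
        try:
            origin = Origin(row["origin"].strip().lower())
        except ValueError:
            raise ValidationError(
                f"{path}: row {i + 2} ({sid!r}): unknown origin "
                f"{row['origin']!r}"
            ) from None
        status_token = row["status"].strip().upper() or "NE"
        if status_token in {"-", "--", "NOT EVALUATED"}:
            status_token = "NE"
        try:
            status = Status(status_token)
        except ValueError:
            raise ValidationError(
                f"{path}: row {i + 2} ({sid!r}): unknown status "
                f"{row['status']!r}"
            ) from None
        extinct_token = str(row.get("extinct", "")).strip().lower()
        if extinct_token in _TRUE_TOKENS:
            extinct = True
        elif extinct_token in _FALSE_TOKENS or extinct_token == "nan":
            extinct = False
        else:
            raise ValidationError(
                f"{path}: row {i + 2} ({sid!r}): unparseable extinct flag "
                f"{extinct_token!r}"
            )
        records.append(SpeciesRecord(sid, origin, status, extinct))
    ids = [r.species_id for r in records]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicated species_id(s): {sorted(dupes)}")
    log.info("read %d species records from %s", len(records), path)
    return records


def write_species_metadata(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "origin": [r.origin.value for r in records],
            "status": [r.status.value for r in records],
            "extinct": [int(r.extinct) for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# occurrence matrices

def read_occurrence(path: str | Path, scenario: str) -> OccurrenceMatrix:
    """Read a binary occurrence CSV (rows = species, columns = basins)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    basin_names = [h.strip() for h in header[1:]]
    dupes = {b for b in basin_names if basin_names.count(b) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicated basin name(s): {sorted(dupes)}")
    df = pd.read_csv(path, dtype=str).fillna("")
    species = [s.strip() for s in df.iloc[:, 0]]
    values = np.zeros((len(species), len(basin_names)), dtype=np.uint8)
    for j, basin in enumerate(basin_names):
        for i, cell in enumerate(df.iloc[:, j + 1]):
            token = str(cell).strip()
            if token not in {"0", "1"}:
                raise ValidationError(
                    f"{path}: non-binary cell {token!r} at species "
                    f"{species[i]!r}, basin {basin!r}"
                )
            values[i, j] = int(token)
    occ = OccurrenceMatrix(scenario, basin_names, species, values)
    log.info("read %s occurrence matrix: %d species x %d basins from %s",
             scenario, occ.n_species, occ.n_basins, path)
    return occ


def write_occurrence(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=True)


# ---------------------------------------------------------------------------
# bracket-notation importer

_BRACKET_RE = re.compile(r"^[\[\(]?\s*(.*?)\s*[\]\)]*$")


def _parse_bracket_cell(cell: str, species: str, basin: str) -> tuple[int, int, int, int]:
    token = str(cell).strip()
    if token in {"", "0"}:
        return (0, 0, 0, 0)
    if token == "1":
        return (1, 1, 1, 1)
    if token == "1/0":
        # extirpated: historically present, gone from current and both futures
        return (1, 0, 0, 0)
    stripped = token.replace("[", "").replace("]", "").replace("(", "").replace(")", "")
    parts = [p.strip() for p in stripped.split(",") if p.strip() != ""]
    if len(parts) == 4 and all(p in {"0", "1"} for p in parts):
        return tuple(int(p) for p in parts)  # type: ignore[return-value]
    raise ValidationError(
        f"malformed bracket cell {cell!r} at species {species!r}, basin {basin!r}"
    )


def _read_table_any(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str).fillna("")
    return pd.read_csv(path, dtype=str).fillna("")


def parse_bracket_table(path: str | Path) -> ScenarioSet:
    """Convert a bracket-notation occurrence table into four aligned matrices.

    Each occupied cell holds ``[h,c,f1,f2]`` presence flags (scenario order:
    historical, current, future-1, future-2); bare ``1``/``0`` cells apply to
    all four scenarios and ``1/0`` marks extirpation (present historically
    only).  Columns named ``origin``/``status``/``extinct`` are ignored here
    (they belong to the metadata table).  Native rows violating monotonic
    extinction (future2 > future1 > current presence) are reported at WARNING
    level, never silently altered.
    """
    df = _read_table_any(path)
    meta_cols = {c for c in df.columns[1:] if c.strip().lower() in
                 {"origin", "status", "extinct", "common_name", "family"}}
    basin_cols = [c for c in df.columns[1:] if c not in meta_cols]
    basins = [c.strip() for c in basin_cols]
    dupes = {b for b in basins if basins.count(b) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicated basin name(s): {sorted(dupes)}")
    species = [str(s).strip() for s in df.iloc[:, 0]]
    stack = np.zeros((4, len(species), len(basins)), dtype=np.uint8)
    for i, sid in enumerate(species):
        for j, col in enumerate(basin_cols):
            quad = _parse_bracket_cell(df.iloc[i][col], sid, basins[j])
            stack[:, i, j] = quad
    matrices = {
        name: OccurrenceMatrix(name, list(basins), list(species), stack[k])
        for k, name in enumerate(SCENARIOS)
    }
    sset = ScenarioSet(matrices)
    for sid, basin, chain in monotonicity_violations(sset):
        log.warning(
            "non-monotonic presence for species %r in basin %r: "
            "historical,current,future1,future2 = %s", sid, basin, chain,
        )
    log.info("parsed bracket table %s: %d species x %d basins x 4 scenarios",
             path, len(species), len(basins))
    return sset


def monotonicity_violations(sset: ScenarioSet) -> list[tuple[str, str, tuple[int, ...]]]:
    """Cells where presence fails future2 <= future1 <= current.

    Under extinction-only scenario construction a species present in a later
    scenario must be present in every earlier one (historical presence is not
    constrained: exotics are absent historically by definition).
    """
    cur = sset["current"].values
    f1 = sset["future1"].values
    f2 = sset["future2"].values
    bad = (f2 > f1) | (f1 > cur)
    out = []
    for i, j in np.argwhere(bad):
        chain = tuple(int(sset[s].values[i, j]) for s in SCENARIOS)
        out.append((sset.species[i], sset.basins[j], chain))
    return out
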