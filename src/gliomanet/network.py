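"""Declarative cell–cytokine network specification.

A :class:`NetworkSpec` is the full declarative model behind the simulator:
the species (cell populations and soluble cytokines), their basal kinetic
parameters, and the Hill-modulated pathway edges through which cytokines
up- or down-regulate cellular processes and each other's secretion.  The
shipped default is a glioblastoma microenvironment with 5 cell types,
15 cytokines and 69 signaling pathways.

Specs are stored as human-editable YAML (one file per network, schema
versioned); :func:`load_network_spec` / :func:`save_network_spec` are the
canonical (de)serializers and round-trip bit-stably.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

SCHEMA_VERSION = 1

CELL = "cell"
CYTOKINE = "cytokine"

CONVERSION_KINDS = ("mutation", "differentiation", "dedifferentiation",
                    "activation", "deactivation")
#: processes a pathway edge may modulate
EDGE_PROCESSES = ("proliferation", "decay", "secretion", "conversion",
                  "recruitment")


class SchemaError(ValueError):
    """Raised when a spec file does not parse against the documented schema."""


class ValidationError(ValueError):
    """Raised when a structurally parseable spec violates model invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "network spec failed validation:\n  - " + "\n  - ".join(violations)
        )


@dataclass
class Species:
    id: str
    name: str
    role: str  # "cell" | "cytokine"
    initial_concentration: float  # cells/ml or pg/ml
    units: str = ""
    description: str = ""

    def __post_init__(self):
        if not self.units:
            self.units = "cells/ml" if self.role == CELL else "pg/ml"


@dataclass
class Conversion:
    """A cell-state change feeding this cell species from ``source_species_id``."""
    id: str
    source_species_id: str
    kind: str  # one of CONVERSION_KINDS
    basal_rate: float  # 1/day


@dataclass
class CellParams:
    species_id: str
    basal_proliferation_rate: float  # 1/day, the basal rate function f
    basal_decay_rate: float          # 1/day
    saturating_concentration: float  # cells/ml, crowding capacity c-bar
    conversions: list[Conversion] = field(default_factory=list)
    angiogenesis_gated: bool = False  # proliferation multiplied by A(t)
    crowding: bool = True  # counts toward the shared crowding density


@dataclass
class Producer:
    cell_species_id: str
    basal_secretion_rate: float  # pg/cell/day


@dataclass
class CytokineParams:
    species_id: str
    producers: list[Producer] = field(default_factory=list)
    half_life: float = 0.5  # days


@dataclass
class HillParams:
    """Saturating response c^n / (K^n + c^n) with amplitude mapping.

    For an up edge the modulation factor is 1 + (a-1)*h, range [1, a] with
    a >= 1 the max fold-change; for a down edge it is 1 - (1-a)*h, range
    (a, 1] with a in [0, 1] the residual fraction at saturation.
    """
    K: float  # half-saturation, units of the source cytokine
    n: float  # Hill coefficient, > 0
    a: float  # effect amplitude


@dataclass
class EdgeTarget:
    species_id: str
    process: str                       # one of EDGE_PROCESSES
    cytokine_id: Optional[str] = None  # for process == "secretion"
    cell_id: Optional[str] = None      # optional: restrict secretion to one producer
    conversion_id: Optional[str] = None  # for process == "conversion"


@dataclass
class PathwayEdge:
    id: str
    source_cytokine_id: str
    target: EdgeTarget
    direction: str  # "up" | "down"
    hill: HillParams
    receptor_scale_param_id: Optional[str] = None


@dataclass
class AngiogenesisParams:
    """Vascular-support multiplier on gated proliferation.

    A(t) = A_min + (1 - A_min) * hill(c_driver; K_A, n_A); the default driver
    is VEGF.  ``receptor_scale_param_id`` lets a virtual-patient receptor
    multiplier act on K_A the same way it acts on pathway-edge K's.
    """
    driver_cytokine_id: str = "VEGF"
    A_min: float = 0.3
    K_A: float = 1.0
    n_A: float = 1.0
    receptor_scale_param_id: Optional[str] = None


@dataclass
class NetworkSpec:
    name: str
    species: list[Species]
    cell_params: list[CellParams]
    cytokine_params: list[CytokineParams]
    edges: list[PathwayEdge]
    angiogenesis: AngiogenesisParams
    schema_version: int = SCHEMA_VERSION
    description: str = ""
    expected_counts: Optional[dict] = None  # {"cells":5,"cytokines":15,"edges":69}

    # -- convenience accessors -------------------------------------------------
    @property
    def cells(self) -> list[Species]:
        return [s for s in self.species if s.role == CELL]

    @property
    def cytokines(self) -> list[Species]:
        return [s for s in self.species if s.role == CYTOKINE]

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def cell_params_for(self, sid: str) -> CellParams:
        for cp in self.cell_params:
            if cp.species_id == sid:
                return cp
        raise KeyError(sid)

    def cytokine_params_for(self, sid: str) -> CytokineParams:
        for cp in self.cytokine_params:
            if cp.species_id == sid:
                return cp
        raise KeyError(sid)

    def tunable_parameters(self) -> list[str]:
        """Enumerate the tunable virtual-patient / sensitivity parameters.

        One production-rate multiplier per cytokine (``prod_<id>``), plus every
        distinct ``receptor_scale_param_id`` declared on edges or on the
        angiogenesis factor.  On the default glioma network this yields
        15 + 14 = 29 parameters.
        """
        params = [f"prod_{c.id}" for c in self.cytokines]
        seen = []
        for e in self.edges:
            rid = e.receptor_scale_param_id
            if rid and rid not in seen:
                seen.append(rid)
        rid = self.angiogenesis.receptor_scale_param_id
        if rid and rid not in seen:
            seen.append(rid)
        return params + sorted(seen)


# ---------------------------------------------------------------------------
# validation


def validate(spec: NetworkSpec) -> list[str]:
    """Return the list of invariant violations (empty iff the spec is usable)."""
    v: list[str] = []
    ids = [s.id for s in spec.species]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        v.append(f"duplicate species ids: {sorted(dup)}")
    id_set = set(ids)
    cell_ids = {s.id for s in spec.species if s.role == CELL}
    cyt_ids = {s.id for s in spec.species if s.role == CYTOKINE}

    for s in spec.species:
        if s.role not in (CELL, CYTOKINE):
            v.append(f"Species({s.id}): unknown role {s.role!r}")
        if s.initial_concentration < 0:
            v.append(f"Species({s.id}): negative initial_concentration")

    covered = set()
    for cp in spec.cell_params:
        tag = f"CellParams({cp.species_id})"
        covered.add(cp.species_id)
        if cp.species_id not in cell_ids:
            v.append(f"{tag}: not a cell species")
            continue
        if cp.basal_proliferation_rate < 0 or cp.basal_decay_rate < 0:
            v.append(f"{tag}: negative basal rate")
        if cp.saturating_concentration <= 0:
            v.append(f"{tag}: saturating_concentration must be > 0")
        conv_ids = [c.id for c in cp.conversions]
        if len(conv_ids) != len(set(conv_ids)):
            v.append(f"{tag}: duplicate conversion ids")
        for c in cp.conversions:
            if c.source_species_id not in cell_ids:
                v.append(f"{tag}: conversion {c.id} source "
                         f"{c.source_species_id!r} is not a cell species")
            if c.kind not in CONVERSION_KINDS:
                v.append(f"{tag}: conversion {c.id} unknown kind {c.kind!r}")
            if c.basal_rate < 0:
                v.append(f"{tag}: conversion {c.id} negative rate")
    missing = cell_ids - covered
    if missing:
        v.append(f"cells without CellParams: {sorted(missing)}")

    covered = set()
    for cp in spec.cytokine_params:
        tag = f"CytokineParams({cp.species_id})"
        covered.add(cp.species_id)
        if cp.species_id not in cyt_ids:
            v.append(f"{tag}: not a cytokine species")
            continue
        if cp.half_life <= 0:
            v.append(f"{tag}: half_life must be > 0")
        for p in cp.producers:
            if p.cell_species_id not in cell_ids:
                v.append(f"{tag}: producer {p.cell_species_id!r} is not a cell")
            if p.basal_secretion_rate < 0:
                v.append(f"{tag}: negative secretion rate for "
                         f"{p.cell_species_id}")
    missing = cyt_ids - covered
    if missing:
        v.append(f"cytokines without CytokineParams: {sorted(missing)}")

    edge_ids = [e.id for e in spec.edges]
    if len(edge_ids) != len(set(edge_ids)):
        v.append("duplicate edge ids")
    conv_lookup = {
        (cp.species_id, c.id)
        for cp in spec.cell_params for c in cp.conversions
    }
    producer_lookup = {
        (cp.species_id, p.cell_species_id)
        for cp in spec.cytokine_params for p in cp.producers
    }
    for e in spec.edges:
        tag = f"PathwayEdge({e.id})"
        if e.source_cytokine_id not in cyt_ids:
            v.append(f"{tag}: source {e.source_cytokine_id!r} is not a cytokine")
        if e.direction not in ("up", "down"):
            v.append(f"{tag}: direction must be 'up' or 'down'")
        h = e.hill
        if h.K <= 0 or h.n <= 0:
            v.append(f"{tag}: Hill K and n must be > 0")
        if e.direction == "up" and h.a < 1:
            v.append(f"{tag}: up-edge amplitude must be >= 1 (max fold-change)")
        if e.direction == "down" and not (0 <= h.a <= 1):
            v.append(f"{tag}: down-edge amplitude must be in [0, 1]")
        t = e.target
        if t.process not in EDGE_PROCESSES:
            v.append(f"{tag}: unknown process {t.process!r}")
            continue
        if t.process == "secretion":
            if t.cytokine_id not in cyt_ids:
                v.append(f"{tag}: secretion target cytokine "
                         f"{t.cytokine_id!r} does not exist")
            elif t.cell_id is not None:
                if (t.cytokine_id, t.cell_id) not in producer_lookup:
                    v.append(f"{tag}: {t.cell_id!r} is not a producer of "
                             f"{t.cytokine_id}")
        elif t.process == "conversion":
            if t.species_id not in cell_ids:
                v.append(f"{tag}: conversion target species "
                         f"{t.species_id!r} does not exist")
            elif (t.species_id, t.conversion_id) not in conv_lookup:
                v.append(f"{tag}: conversion {t.conversion_id!r} not found "
                         f"on {t.species_id}")
        elif t.process in ("proliferation", "recruitment"):
            if t.species_id not in cell_ids:
                v.append(f"{tag}: target species {t.species_id!r} "
                         f"is not a cell")
        elif t.process == "decay":
            if t.species_id not in id_set:
                v.append(f"{tag}: target species {t.species_id!r} "
                         "does not exist")

    ang = spec.angiogenesis
    if ang.driver_cytokine_id not in cyt_ids:
        v.append(f"angiogenesis driver {ang.driver_cytokine_id!r} "
                 "is not a cytokine")
    if not (0 < ang.A_min <= 1):
        v.append("angiogenesis A_min must be in (0, 1]")
    if ang.K_A <= 0 or ang.n_A <= 0:
        v.append("angiogenesis K_A and n_A must be > 0")

    if spec.expected_counts:
        exp = spec.expected_counts
        got = {"cells": len(cell_ids), "cytokines": len(cyt_ids),
               "edges": len(spec.edges)}
        for key, want in exp.items():
            if got.get(key) != want:
                v.append(f"expected {want} {key}, found {got.get(key)}")
    return v


def check_valid(spec: NetworkSpec) -> NetworkSpec:
    violations = validate(spec)
    if violations:
        raise ValidationError(violations)
    return spec


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: NetworkSpec) -> dict:
    d = asdict(spec)
    # drop Nones for a tidier file; loader restores defaults
    def prune(obj):
        if isinstance(obj, dict):
            return {k: prune(x) for k, x in obj.items() if x is not None}
        if isinstance(obj, list):
            return [prune(x) for x in obj]
        if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
            return obj.item()  # numpy scalars -> plain python
        return obj
    return prune(d)


def _dict_to_spec(d: dict, origin: str = "<dict>") -> NetworkSpec:
    try:
        species = [Species(**s) for s in d["species"]]
        cell_params = [
            CellParams(
                species_id=c["species_id"],
                basal_proliferation_rate=c["basal_proliferation_rate"],
                basal_decay_rate=c["basal_decay_rate"],
                saturating_concentration=c["saturating_concentration"],
                conversions=[Conversion(**cv) for cv in c.get("conversions", [])],
                angiogenesis_gated=c.get("angiogenesis_gated", False),
                crowding=c.get("crowding", True),
            )
            for c in d["cell_params"]
        ]
        cytokine_params = [
            CytokineParams(
                species_id=c["species_id"],
                producers=[Producer(**p) for p in c.get("producers", [])],
                half_life=c["half_life"],
            )
            for c in d["cytokine_params"]
        ]
        edges = [
            PathwayEdge(
                id=e["id"],
                source_cytokine_id=e["source_cytokine_id"],
                target=EdgeTarget(**e["target"]),
                direction=e["direction"],
                hill=HillParams(**e["hill"]),
                receptor_scale_param_id=e.get("receptor_scale_param_id"),
            )
            for e in d["edges"]
        ]
        ang = AngiogenesisParams(**d.get("angiogenesis", {}))
        return NetworkSpec(
            name=d.get("name", "unnamed"),
            species=species,
            cell_params=cell_params,
            cytokine_params=cytokine_params,
            edges=edges,
            angiogenesis=ang,
            schema_version=d.get("schema_version", SCHEMA_VERSION),
            description=d.get("description", ""),
            expected_counts=d.get("expected_counts"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{origin}: malformed network spec: {exc}") from exc


def load_network_spec(path: str | Path) -> NetworkSpec:
    """Load and fully validate a network spec from a YAML file."""
    path = Path(path)
    try:
        with open(path) as fh:
            d = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return check_valid(_dict_to_spec(d, origin=str(path)))


def save_network_spec(spec: NetworkSpec, path: str | Path) -> None:
    """Canonical serializer; write(load(x)) == read-back of x bit-stably."""
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False, width=100)


def default_glioma_spec() -> NetworkSpec:
    """The shipped glioblastoma microenvironment network.

    5 cell populations (quiescent and activated stem-like cells, glioma
    cells, astrocytes, microglia), 15 cytokines, and 69 Hill-modulated
    signaling pathways; initial state is the normal-brain condition with
    zero glioma cells.  The edge roster is a reconstruction from the
    interactions reported for human GBM and ships as an editable data file.
    """
    ref = importlib.resources.files("gliomanet.data") / "glioma_default.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_network_spec(p)


def spec_hash(spec: NetworkSpec) -> str:
    """Stable short hash of the canonical serialization (provenance metadata)."""
    import hashlib
    payload = yaml.safe_dump(_spec_to_dict(spec), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
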