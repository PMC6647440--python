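"""Vascular network representation.

A :class:`NetworkModel` is a directed graph of 1D vessel segments joined at
junctions, terminated by lumped vascular beds, and (for closed-loop networks)
attached to the four-chamber heart through the aortic/pulmonary valves and the
atrial inflows.  Vessel groups that exist as several parallel copies (e.g. the
four arcuate or fifty radial/spiral arteries per uterine level) are stored as a
single effective segment with a ``multiplicity``; the solver carries the
single-vessel flow and applies the multiplicity in junction and bed mass
balances.

File formats: a CSV with columns
``id,name,region,side,length_cm,area_np_cm2,area_p_cm2,multiplicity,parent_ids,bed_id``
(the packaged utero-ovarian table), and a JSON equivalent that additionally
carries vascular-bed specs and heart attachment points (the packaged reduced
closed-loop network).
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from . import parameters as par
from .units import MMHG

#: Interpolation weight between non-pregnant and late-pregnancy reference
#: areas per gestational stage.  Only the NP and late-pregnancy columns are
#: tabulated; intermediate trimesters interpolate linearly (configurable).
STAGE_AREA_WEIGHT = {"PP": 0.0, "T1": 1.0 / 3.0, "T2": 2.0 / 3.0, "T3": 1.0}

STAGES = ("T1", "T2", "T3", "PP")


class NetworkError(ValueError):
    """Raised for malformed network descriptions."""


@dataclass
class VesselSegment:
    id: int
    name: str
    length: float                 # cm
    area_ref_np: float            # cm^2, non-pregnant reference A0
    area_ref_p: float             # cm^2, late-pregnancy reference A0
    multiplicity: int = 1
    region: str = "systemic_artery"
    side: str = "central"
    parent_ids: tuple = ()        # upstream segment ids, or tokens 'AV'/'PV'/'bed:<id>'
    bed_id: object = None         # downstream bed id, or 'RA'/'LA' for atrial inflow
    c0_override: float | None = None   # cm/s, wins over the wave-speed law
    is_vena_cava: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise NetworkError(f"segment {self.id}: non-positive length {self.length}")
        if self.area_ref_np <= 0 or self.area_ref_p <= 0:
            raise NetworkError(f"segment {self.id}: non-positive reference area")
        if self.multiplicity < 1:
            raise NetworkError(f"segment {self.id}: multiplicity must be >= 1")
        if self.region not in par.REGIONS:
            raise NetworkError(f"segment {self.id}: unknown region {self.region!r}")

    def area_ref(self, stage: str) -> float:
        """Reference area at a gestational stage (NP/P interpolation)."""
        w = STAGE_AREA_WEIGHT[stage]
        return (1.0 - w) * self.area_ref_np + w * self.area_ref_p


@dataclass(frozen=True)
class JunctionSpec:
    """Vessel ends meeting at a point: conservation of mass and continuity of
    static pressure are enforced across all attached ends."""

    parent_ids: tuple   # segments whose outlet attaches
    child_ids: tuple    # segments whose inlet attaches

    def __post_init__(self):
        ids = list(self.parent_ids) + list(self.child_ids)
        if len(ids) < 2:
            raise NetworkError(f"junction {ids}: needs at least 2 attachments")
        if len(set(ids)) != len(ids):
            raise NetworkError(f"junction {ids}: segment appears twice")


@dataclass
class VascularBedSpec:
    id: int
    name: str
    arterial_terminal_ids: list = field(default_factory=list)
    venous_terminal_ids: list = field(default_factory=list)
    r0_total: float = float("nan")        # dyn s/cm^5 at p_tm0 (NaN until estimated)
    compliance_total: float = float("nan")  # cm^5/dyn
    p_tm0: float = float("nan")           # dyn/cm^2
    p_zf: float = par.P_ZF_MMHG * MMHG    # dyn/cm^2
    kind: str = "pressure_dependent"      # or 'coronary'
    alpha: float = float("nan")           # cardiac-output fraction hint

    def validate(self):
        if not math.isnan(self.r0_total) and self.r0_total <= 0:
            raise NetworkError(f"bed {self.id}: non-positive R0")
        if not math.isnan(self.compliance_total) and self.compliance_total <= 0:
            raise NetworkError(f"bed {self.id}: non-positive compliance")
        if not math.isnan(self.p_tm0) and self.p_zf >= self.p_tm0:
            raise NetworkError(f"bed {self.id}: p_zf must be below p_tm0")


@dataclass(frozen=True)
class ParticipantInfo:
    label: str
    age: float
    height: float  # cm
    stage: str

    def __post_init__(self):
        if self.height <= 0:
            raise NetworkError("participant height must be positive")
        if self.stage not in STAGES:
            raise NetworkError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class ValveSite:
    """A venous valve located ``position`` cm from the inlet of a segment."""

    segment_id: int
    position: float


@dataclass
class NetworkModel:
    segments: dict = field(default_factory=dict)   # id -> VesselSegment
    beds: dict = field(default_factory=dict)       # id -> VascularBedSpec
    heart: dict = field(default_factory=dict)      # 'AV'/'PV' -> seg id; 'RA'/'LA' -> [seg ids]
    closed_loop: bool = False
    valve_sites: list = field(default_factory=list)

    # ------------------------------------------------------------------ graph
    @property
    def junctions(self) -> list[JunctionSpec]:
        """Junctions derived from segment parent lists (grouped by the set of
        upstream segments feeding a point)."""
        groups: dict[tuple, list[int]] = {}
        for seg in self.segments.values():
            parents = tuple(sorted(p for p in seg.parent_ids if isinstance(p, int)))
            if parents:
                groups.setdefault(parents, []).append(seg.id)
        out = []
        for parents, children in sorted(groups.items()):
            out.append(JunctionSpec(parents, tuple(sorted(children))))
        return out

    def children_of(self, seg_id: int) -> list[int]:
        return [s.id for s in self.segments.values()
                if seg_id in [p for p in s.parent_ids if isinstance(p, int)]]

    # -------------------------------------------------------------- validation
    def validate(self):
        seen = set()
        for sid, seg in self.segments.items():
            if sid != seg.id:
                raise NetworkError(f"segment key {sid} != id {seg.id}")
            if sid in seen:
                raise NetworkError(f"duplicate segment id {sid}")
            seen.add(sid)
        for seg in self.segments.values():
            for p in seg.parent_ids:
                if isinstance(p, int) and p not in self.segments:
                    raise NetworkError(f"segment {seg.id}: dangling parent {p}")
                if isinstance(p, str) and p.startswith("bed:"):
                    bid = int(p.split(":", 1)[1])
                    if bid not in self.beds:
                        raise NetworkError(f"segment {seg.id}: dangling bed ref {p}")
            if isinstance(seg.bed_id, int) and seg.bed_id not in self.beds:
                raise NetworkError(f"segment {seg.id}: dangling bed {seg.bed_id}")
        for bed in self.beds.values():
            bed.validate()
            for t in list(bed.arterial_terminal_ids) + list(bed.venous_terminal_ids):
                if t not in self.segments:
                    raise NetworkError(f"bed {bed.id}: terminal {t} does not exist")
        # each outlet feeds at most one junction group by construction; check
        # connectivity of the undirected graph
        if self.segments and not self._connected():
            raise NetworkError("network graph is not connected")
        if self.closed_loop:
            for seg in self.segments.values():
                if not self.children_of(seg.id) and seg.bed_id is None:
                    raise NetworkError(
                        f"closed loop: terminal segment {seg.id} attaches to nothing")

    def _connected(self) -> bool:
        ids = list(self.segments)
        adj: dict[object, set] = {i: set() for i in ids}
        def link(a, b):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for seg in self.segments.values():
            for p in seg.parent_ids:
                link(seg.id, p if isinstance(p, int) else str(p))
            if seg.bed_id is not None:
                link(seg.id, f"sink:{seg.bed_id}")
        # beds connect their arterial sink to their venous source
        for bed in self.beds.values():
            link(f"sink:{bed.id}", f"bed:{bed.id}")
        # the heart links AV/PV inlets with RA/LA returns
        for key in ("AV", "PV", "RA", "LA"):
            if key in self.heart:
                v = self.heart[key]
                for s in (v if isinstance(v, (list, tuple)) else [v]):
                    link("heart", s)
                link("heart", key)
        start = ids[0]
        stack, seen = [start], {start}
        while stack:
            for nb in adj.get(stack.pop(), ()):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return all(i in seen for i in ids)


# ---------------------------------------------------------------- geometry ops

def area_to_diameter(area: float) -> float:
    """Circular-equivalent diameter (cm) of a cross-sectional area (cm^2)."""
    if area <= 0:
        raise ValueError(f"non-positive area {area}")
    return 2.0 * math.sqrt(area / math.pi)


def diameter_to_area(diameter: float) -> float:
    return math.pi * (diameter / 2.0) ** 2


def murray_fill(parent_diameter: float, n_children: int, split_weights=None,
                exponent: float = par.MURRAY_EXPONENT):
    """Fill child diameters so that sum(d_i^k) = D^k (Murray-type law).

    ``split_weights`` are relative weights of the children's d^k shares;
    equal split by default.
    """
    if parent_diameter <= 0:
        raise ValueError("parent diameter must be positive")
    if n_children < 1:
        raise ValueError("need at least one child")
    if split_weights is None:
        w = np.ones(n_children)
    else:
        w = np.asarray(split_weights, dtype=float)
        if len(w) != n_children or np.any(w <= 0):
            raise ValueError("split_weights must be positive, one per child")
    w = w / w.sum()
    return [parent_diameter * wi ** (1.0 / exponent) for wi in w]


def murray_flow_weights(diameters, exponent: float = par.MURRAY_EXPONENT):
    """Relative flow shares of parallel distal vessels, proportional to d^k."""
    d = np.asarray(diameters, dtype=float)
    shares = d ** exponent
    return shares / shares.sum()


def vein_from_artery(artery_area: float) -> float:
    """Vein area from its companion artery (vein diameter 1.25 x artery).

    Used only when the vein is absent from the network table; tabulated values
    always win.
    """
    if artery_area <= 0:
        raise ValueError("non-positive artery area")
    return 1.25 ** 2 * artery_area


def init_wave_speed(diameter: float, region: str) -> float:
    """Reference wave speed c0 (cm/s) from the empirical stiffness law
    c0^2 = (2/(3 rho)) (k1 exp(k2 D0/2) + k3)."""
    if diameter <= 0:
        raise ValueError("non-positive diameter")
    k1, k2, k3 = par.WAVE_SPEED_COEFFS[region]
    val = 2.0 / (3.0 * par.RHO) * (k1 * math.exp(k2 * diameter / 2.0) + k3)
    if val <= 0:
        raise ValueError(f"negative wave-speed radicand for region {region}")
    return math.sqrt(val)


def wall_viscosity(area: float, region: str) -> float:
    """Voigt wall-viscosity coefficient Gamma (g/s).

    Systemic (and hepatic-portal) arteries follow Gamma = b1/D + b0; systemic
    veins and both pulmonary sides use a constant 200 g/s.
    """
    if area <= 0:
        raise ValueError("non-positive area")
    if region in ("systemic_artery", "coronary_artery"):
        d = area_to_diameter(area)
        return par.WALL_VISC_B1 / d + par.WALL_VISC_B0
    return par.WALL_VISC_CONST


def scale_lengths(network: NetworkModel, participant: ParticipantInfo,
                  base_height: float = par.BASE_HEIGHT_CM) -> NetworkModel:
    """Scale every vessel length by gamma = height/base height (areas fixed)."""
    gamma = participant.height / base_height
    segs = {sid: replace(seg, length=seg.length * gamma)
            for sid, seg in network.segments.items()}
    return replace_segments(network, segs)


def replace_segments(network: NetworkModel, segments: dict) -> NetworkModel:
    return NetworkModel(segments=segments, beds=dict(network.beds),
                        heart=dict(network.heart), closed_loop=network.closed_loop,
                        valve_sites=list(network.valve_sites))


def place_venous_valves(network: NetworkModel) -> NetworkModel:
    """Insert venous valve sites every 4 cm of cumulative systemic-vein path
    length, walking from the venous origins towards the heart; the venae cavae
    carry none.  The valve's maximum orifice is the local vessel area, recorded
    at simulation time."""
    spacing = par.VENOUS_VALVE_SPACING_CM
    sites: list[ValveSite] = []
    venous = {s.id for s in network.segments.values()
              if s.region == "systemic_vein" and not s.is_vena_cava}
    # roots: venous segments fed by a bed (or with no venous parents)
    def venous_parents(seg):
        return [p for p in seg.parent_ids if isinstance(p, int) and p in venous]
    roots = [sid for sid in venous if not venous_parents(network.segments[sid])]
    seen = set()
    stack = [(sid, 0.0) for sid in sorted(roots)]
    while stack:
        sid, offset = stack.pop()
        if sid in seen:
            continue
        seen.add(sid)
        seg = network.segments[sid]
        # valves fall where cumulative length crosses multiples of the spacing
        n0 = math.floor(offset / spacing)
        n1 = math.floor((offset + seg.length) / spacing)
        for n in range(n0 + 1, n1 + 1):
            pos = n * spacing - offset
            if pos < seg.length:  # a valve exactly at the outlet belongs downstream
                sites.append(ValveSite(sid, pos))
        for child in network.children_of(sid):
            if child in venous:
                stack.append((child, offset + seg.length))
    out = replace_segments(network, dict(network.segments))
    out.valve_sites = sorted(sites, key=lambda v: (v.segment_id, v.position))
    return out


# ------------------------------------------------------------------- file I/O

CSV_HEADER = ["id", "name", "region", "side", "length_cm", "area_np_cm2",
              "area_p_cm2", "multiplicity", "parent_ids", "bed_id"]


def _parse_parents(text: str) -> tuple:
    out = []
    for tok in str(text).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        out.append(int(tok) if tok.lstrip("-").isdigit() else tok)
    return tuple(out)


def _parse_bed(text: str):
    text = str(text).strip()
    if not text:
        return None
    return int(text) if text.lstrip("-").isdigit() else text


def _segment_from_row(row: dict, where: str) -> VesselSegment:
    try:
        return VesselSegment(
            id=int(row["id"]), name=str(row["name"]).strip(),
            region=str(row["region"]).strip(), side=str(row.get("side", "central") or "central"),
            length=float(row["length_cm"]),
            area_ref_np=float(row["area_np_cm2"]), area_ref_p=float(row["area_p_cm2"]),
            multiplicity=int(row.get("multiplicity", 1) or 1),
            parent_ids=_parse_parents(row.get("parent_ids", "")),
            bed_id=_parse_bed(row.get("bed_id", "")),
            c0_override=(float(row["c0_cm_s"]) if row.get("c0_cm_s") else None),
            is_vena_cava=str(row.get("is_vena_cava", "")).strip().lower() in ("1", "true", "yes"),
        )
    except (KeyError, ValueError) as exc:
        raise NetworkError(f"{where}: {exc}") from exc


def load_network(source) -> NetworkModel:
    """Load a network table (CSV or JSON, by extension).

    CSV carries segments only (open fragments such as the utero-ovarian table);
    JSON additionally carries beds, heart attachments and the closed-loop flag.
    """
    path = Path(source)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        model = NetworkModel(closed_loop=bool(doc.get("closed_loop", False)))
        for row in doc.get("segments", []):
            seg = VesselSegment(
                id=int(row["id"]), name=row["name"], region=row["region"],
                side=row.get("side", "central"), length=float(row["length_cm"]),
                area_ref_np=float(row["area_np_cm2"]), area_ref_p=float(row["area_p_cm2"]),
                multiplicity=int(row.get("multiplicity", 1)),
                parent_ids=tuple(row.get("parent_ids", [])),
                bed_id=row.get("bed_id"),
                c0_override=row.get("c0_cm_s"),
                is_vena_cava=bool(row.get("is_vena_cava", False)),
            )
            if seg.id in model.segments:
                raise NetworkError(f"duplicate segment id {seg.id}")
            model.segments[seg.id] = seg
        for row in doc.get("beds", []):
            bed = VascularBedSpec(
                id=int(row["id"]), name=row["name"],
                arterial_terminal_ids=list(row.get("arterial_terminal_ids", [])),
                venous_terminal_ids=list(row.get("venous_terminal_ids", [])),
                r0_total=float(row.get("r0_total", "nan")),
                compliance_total=float(row.get("compliance_total", "nan")),
                p_tm0=float(row.get("p_tm0", "nan")),
                p_zf=float(row.get("p_zf", par.P_ZF_MMHG * MMHG)),
                kind=row.get("kind", "pressure_dependent"),
                alpha=float(row.get("alpha", "nan")),
            )
            model.beds[bed.id] = bed
        model.heart = dict(doc.get("heart", {}))
        if not model.segments:
            raise NetworkError("no segments")
        model.validate()
        return model

    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise NetworkError("no segments")
    model = NetworkModel()
    for i, row in enumerate(rows):
        seg = _segment_from_row(row, where=f"{path.name}:row {i + 2}")
        if seg.id in model.segments:
            raise NetworkError(f"{path.name}: duplicate segment id {seg.id}")
        model.segments[seg.id] = seg
    # beds referenced by segments are created implicitly for open fragments
    _ensure_referenced_beds(model)
    if not model.segments:
        raise NetworkError("no segments")
    model.validate()
    return model


def _ensure_referenced_beds(model: NetworkModel):
    for seg in model.segments.values():
        refs = []
        if isinstance(seg.bed_id, int):
            refs.append((seg.bed_id, "arterial", seg.id))
        for p in seg.parent_ids:
            if isinstance(p, str) and p.startswith("bed:"):
                refs.append((int(p.split(":", 1)[1]), "venous", seg.id))
        for bid, side, sid in refs:
            bed = model.beds.setdefault(bid, VascularBedSpec(id=bid, name=f"bed{bid}"))
            target = (bed.arterial_terminal_ids if side == "arterial"
                      else bed.venous_terminal_ids)
            if sid not in target:
                target.append(sid)


def write_network(model: NetworkModel, dest):
    """Write a network to CSV or JSON (by extension); round-trips with
    :func:`load_network`."""
    path = Path(dest)
    if path.suffix.lower() == ".json":
        doc = {"closed_loop": model.closed_loop, "segments": [], "beds": [],
               "heart": model.heart}
        for seg in sorted(model.segments.values(), key=lambda s: s.id):
            doc["segments"].append({
                "id": seg.id, "name": seg.name, "region": seg.region,
                "side": seg.side, "length_cm": seg.length,
                "area_np_cm2": seg.area_ref_np, "area_p_cm2": seg.area_ref_p,
                "multiplicity": seg.multiplicity,
                "parent_ids": list(seg.parent_ids), "bed_id": seg.bed_id,
                "c0_cm_s": seg.c0_override, "is_vena_cava": seg.is_vena_cava,
            })
        for bed in sorted(model.beds.values(), key=lambda b: b.id):
            doc["beds"].append({
                "id": bed.id, "name": bed.name,
                "arterial_terminal_ids": list(bed.arterial_terminal_ids),
                "venous_terminal_ids": list(bed.venous_terminal_ids),
                "r0_total": bed.r0_total, "compliance_total": bed.compliance_total,
                "p_tm0": bed.p_tm0, "p_zf": bed.p_zf, "kind": bed.kind,
                "alpha": bed.alpha,
            })
        path.write_text(json.dumps(doc, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for seg in sorted(model.segments.values(), key=lambda s: s.id):
            writer.writerow([
                seg.id, seg.name, seg.region, seg.side, repr(seg.length),
                repr(seg.area_ref_np), repr(seg.area_ref_p), seg.multiplicity,
                ";".join(str(p) for p in seg.parent_ids),
                "" if seg.bed_id is None else seg.bed_id,
            ])


def packaged_path(name: str):
    """Path of a packaged data fixture."""
    return resources.files("uteroflow.data").joinpath(name)


def load_packaged(name: str) -> NetworkModel:
    with resources.as_file(packaged_path(name)) as p:
        return load_network(p)


# ------------------------------------------------------- utero-ovarian builder

#: Bed ids used by the utero-ovarian fragment
UO_BEDS = {1: "ovary_left", 2: "ovary_right", 3: "fundus", 4: "uterus_a",
           5: "placenta", 6: "uterus_b", 7: "cervix_vagina"}

#: id offset applied to the right-side copy of the fragment
RIGHT_SIDE_OFFSET = 400


def build_uteroovarian(stage: str, sides: str = "both") -> NetworkModel:
    """Build the utero-ovarian loop from the packaged vessel table.

    The fragment is an open sub-network: arterial inlets are the ovarian artery
    (fed from the aorta) and the uterine artery (fed from the internal iliac);
    venous outlets are their mirrors.  ``sides``:

    - ``"both"``: left and right copies, mirrored, sharing the central beds
      (fundus, uterus, placenta, cervix|vagina), with per-side ovary beds.
    - ``"left"``: a single side.
    - ``"merged"``: a single side whose segment multiplicities are doubled —
      exactly the symmetric solution at half the unknown count.

    The placenta bed exists only for pregnant stages; post-partum its spiral
    arteries terminate in the uterus bed instead.
    """
    if stage not in STAGES:
        raise NetworkError(f"unknown stage {stage!r}")
    if sides not in ("both", "left", "merged"):
        raise NetworkError(f"unknown sides mode {sides!r}")
    base = load_packaged("uteroovarian_table1.csv")
    model = NetworkModel()
    for bid, name in UO_BEDS.items():
        if bid == 2 and sides != "both":
            continue
        if bid == 5 and stage == "PP":
            continue
        model.beds[bid] = VascularBedSpec(id=bid, name=name)

    def add_side(offset: int, side: str, mult_scale: int):
        for seg in base.segments.values():
            bed_id = seg.bed_id
            if bed_id == 5 and stage == "PP":
                bed_id = 6          # placental spirals revert to the uterus wall
            if bed_id == 1 and side == "right":
                bed_id = 2          # per-side ovary bed
            parents = tuple(p + offset if isinstance(p, int) else p
                            for p in seg.parent_ids)
            new = replace(seg, id=seg.id + offset, side=side, parent_ids=parents,
                          bed_id=bed_id, multiplicity=seg.multiplicity * mult_scale)
            model.segments[new.id] = new
            if bed_id is not None:
                bed = model.beds[bed_id]
                target = (bed.arterial_terminal_ids if new.region.endswith("artery")
                          else bed.venous_terminal_ids)
                target.append(new.id)
            # venous bed-origin references
            for p in new.parent_ids:
                if isinstance(p, str) and p.startswith("bed:"):
                    bid = int(p.split(":", 1)[1])
                    if bid == 5 and stage == "PP":
                        bid = 6
                    if bid == 1 and side == "right":
                        bid = 2
                    fixed = tuple(f"bed:{bid}" if q == p else q for q in new.parent_ids)
                    new.parent_ids = fixed
                    model.beds[bid].venous_terminal_ids.append(new.id)

    mult = 2 if sides == "merged" else 1
    add_side(0, "left", mult)
    if sides == "both":
        add_side(RIGHT_SIDE_OFFSET, "right", 1)
    # bed_id lists were appended through both paths; tidy duplicates
    for bed in model.beds.values():
        bed.arterial_terminal_ids = sorted(set(bed.arterial_terminal_ids))
        bed.venous_terminal_ids = sorted(set(bed.venous_terminal_ids))
    model.validate()
    return model


#: exposed couplings of the fragment (left side ids; add RIGHT_SIDE_OFFSET for
#: the right copy): arterial inlets and venous outlets
UO_ARTERIAL_INLETS = (62, 80)
UO_VENOUS_OUTLETS = (270, 268)
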