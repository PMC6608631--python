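"""Seeded, ground-truth-annotated synthetic structures in PDB format.

Emulates the motifs seen in rhenium-soaked lysozyme crystals without any
real protein fold: an ideal fac-Re(CO)3(H2O)2(N-His) adduct on an
imidazole, lone Re atoms on Asp/Glu-type carboxylates (monodentate,
bidentate or asymmetric), the ideal cubane cluster Re4(mu3-OH)4(CO)12,
bare metal atoms and decoy waters.  Each generated file carries a JSON
sidecar of ground-truth annotations (expected contacts and their classes,
cluster nuclearities, quasi bite angles) computed from the construction
parameters before noise, so analysis results can be checked in a closed
loop.

Construction defaults: cubane Re–Re edge 3.43 Å (mean of the 3.46/3.40 Å
typical cluster distances), Re–O(mu3-OH) 2.17 Å, Re–C 1.92 Å, C–O 1.15 Å,
Re–N(imidazole) 2.16 Å, Re–Br 2.61 Å — standard small-molecule magnitudes
where no protein-crystal value exists, all exposed as parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .metal_sites import RadiiTable, classify_contact
from .pdbio import AtomRecord, StructureModel, write_pdb

__all__ = [
    "MotifSpec",
    "SyntheticSpec",
    "GroundTruth",
    "build_cubane",
    "build_his_site",
    "build_carboxylate_site",
    "generate_structure",
    "write_pdb",
]

MOTIF_KINDS = ("his_site", "carboxylate_site", "cubane", "lone_metal", "decoy_water")

#: ideal carboxylate geometry
CARBOXYLATE_CO = 1.25  # Å
CARBOXYLATE_OCO = 124.0  # degrees
#: imidazole ring bond length used for the ideal pentagon
IMIDAZOLE_SIDE = 1.37  # Å
#: aqua ligand Re–O distance
RE_AQUA = 2.18  # Å
RE_BR = 2.61  # Å


@dataclass
class MotifSpec:
    """One motif to place: kind, position, occupancy and orientation."""

    kind: str
    center: Sequence[float] = (0.0, 0.0, 0.0)
    occupancy: float = 1.0
    orientation: object | None = None  # None (identity), "random", Rotation, matrix, quat
    chain: str = "A"
    residue_number: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic structure."""

    seed: int = 0
    motifs: list[MotifSpec] = field(default_factory=list)
    noise_sigma: float = 0.0  # Å, Gaussian per coordinate
    dpi: float | None = None  # stamped into the output header
    min_separation: float = 8.0  # Å between motif centers
    allow_close: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(source).read_text())
        motifs = [MotifSpec(**m) for m in raw.pop("motifs", [])]
        return cls(motifs=motifs, **raw)


@dataclass
class GroundTruth:
    """Pre-noise expectations recorded while building a structure."""

    contacts: list[dict] = field(default_factory=list)
    cluster_nuclearities: list[int] = field(default_factory=list)
    bite_angles: list[dict] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "contacts": self.contacts,
            "cluster_nuclearities": sorted(self.cluster_nuclearities, reverse=True),
            "bite_angles": self.bite_angles,
        }

    def write_json(self, destination: str | Path) -> None:
        Path(destination).write_text(json.dumps(self.to_dict(), indent=1))


def _atom(name, element, resname, xyz, het=True, occ=1.0, b=20.0):
    return AtomRecord(
        serial=1, name=name, element=element, residue_name=resname,
        chain="A", residue_number=1, xyz=np.asarray(xyz, float),
        occupancy=occ, b_factor=b, is_het=het,
    )


def build_cubane(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    edge: float = 3.43,
    re_o: float = 2.17,
    re_c: float = 1.92,
    c_o: float = 1.15,
    occupancy: float = 1.0,
    orientation: object | None = None,
) -> list[AtomRecord]:
    """Ideal Re4(mu3-OH)4(CO)12 cubane cluster.

    Four Re at the vertices of a regular tetrahedron of the given edge,
    one mu3-OH oxygen over each face at ``re_o`` from all three of that
    face's rheniums, and three carbonyls per Re trans to its hydroxides
    (pseudo-octahedral metal environments, CO pointing outward).
    """
    if min(edge, re_o, re_c, c_o) <= 0:
        raise ValueError("all construction lengths must be positive")
    face_circumradius = edge / math.sqrt(3.0)
    if re_o < face_circumradius:
        raise ValueError(
            f"re_o={re_o} is shorter than the face circumradius {face_circumradius:.3f}"
        )
    s = edge / (2.0 * math.sqrt(2.0))
    verts = s * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    atoms = [_atom("RE", "Re", "RE4", v, occ=occupancy) for v in verts]
    # mu3-OH over each face, offset along the outward face normal
    t = math.sqrt(re_o**2 - face_circumradius**2)
    oh_positions: dict[frozenset, np.ndarray] = {}
    for face in combinations(range(4), 3):
        g = verts[list(face)].mean(axis=0)
        normal = g / np.linalg.norm(g)
        oh_positions[frozenset(face)] = g + t * normal
    for i, (face, pos) in enumerate(sorted(oh_positions.items(), key=lambda kv: sorted(kv[0])), 1):
        atoms.append(_atom(f"O{i}", "O", "RE4", pos, occ=occupancy))
    # three carbonyls per Re, each trans to one of its mu3-OH oxygens
    n_c = 0
    for vi in range(4):
        for face, oh in sorted(oh_positions.items(), key=lambda kv: sorted(kv[0])):
            if vi not in face:
                continue
            n_c += 1
            u = verts[vi] - oh
            u = u / np.linalg.norm(u)
            atoms.append(_atom(f"C{n_c}", "C", "RE4", verts[vi] + re_c * u, occ=occupancy))
            atoms.append(
                _atom(f"OC{n_c}", "O", "RE4", verts[vi] + (re_c + c_o) * u, occ=occupancy)
            )
    return _place(atoms, center, orientation)


def build_his_site(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    re_n: float = 2.16,
    orientation: object | None = None,
    occupancy: float = 1.0,
    bromide: bool = False,
    re_br: float = RE_BR,
) -> list[AtomRecord]:
    """fac-Re(CO)3(H2O)2(N-His) adduct on an ideal imidazole ring.

    The metal sits in an octahedral environment: three mutually cis
    carbonyls, two aqua ligands and the histidine NE2 at ``re_n``.  With
    ``bromide`` one aqua is replaced by Br at ``re_br`` (the H2O/Br
    positional-disorder situation seen in long-soaked crystals).
    """
    if re_n <= 0:
        raise ValueError("re_n must be positive")
    e1, e2, e3 = np.eye(3)
    atoms = [_atom("RE", "Re", "RRE", np.zeros(3), occ=occupancy)]
    for i, axis in enumerate((e1, e2, e3), 1):
        atoms.append(_atom(f"C{i}", "C", "RRE", 1.92 * axis, occ=occupancy))
        atoms.append(_atom(f"OC{i}", "O", "RRE", (1.92 + 1.15) * axis, occ=occupancy))
    if bromide:
        atoms.append(_atom("BR", "Br", "RRE", -re_br * e1, occ=occupancy))
    else:
        atoms.append(_atom("OW1", "O", "RRE", -RE_AQUA * e1, occ=occupancy))
    atoms.append(_atom("OW2", "O", "RRE", -RE_AQUA * e2, occ=occupancy))
    # ideal imidazole: regular pentagon in the x-z plane, NE2 lone pair
    # pointing at the metal along -e3
    r5 = IMIDAZOLE_SIDE / (2.0 * math.sin(math.pi / 5.0))
    ring_center = -(re_n + r5) * e3
    ring_names = ["NE2", "CE1", "ND1", "CG", "CD2"]
    ring_elements = ["N", "C", "N", "C", "C"]
    for i, (name, elem) in enumerate(zip(ring_names, ring_elements)):
        theta = 2.0 * math.pi * i / 5.0
        pos = ring_center + r5 * (math.cos(theta) * e3 + math.sin(theta) * e1)
        atoms.append(_atom(name, elem, "HIS", pos, het=False, occ=1.0))
    return _place(atoms, center, orientation)


def build_carboxylate_site(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    mode: str = "monodentate",
    re_o: float = 2.2,
    occupancy: float = 1.0,
    re_o2: float | None = None,
    orientation: object | None = None,
) -> list[AtomRecord]:
    """Lone Re on an ideal carboxylate (Asp-style CG/OD1/OD2).

    monodentate: Re on the OD2 lone-pair direction at ``re_o``, the other
    oxygen well beyond bonding range.  bidentate: Re equidistant ``re_o``
    from both oxygens on the carboxylate bisector.  Supplying ``re_o2``
    places Re at ``re_o`` from OD2 and ``re_o2`` from OD1 (asymmetric
    one-bond-plus-long-contact pattern).
    """
    if mode not in ("monodentate", "bidentate"):
        raise ValueError(f"unknown mode {mode!r}")
    half = math.radians(CARBOXYLATE_OCO / 2.0)
    od1 = CARBOXYLATE_CO * np.array([math.cos(half), math.sin(half), 0.0])
    od2 = CARBOXYLATE_CO * np.array([math.cos(half), -math.sin(half), 0.0])
    atoms = [
        _atom("CB", "C", "ASP", np.array([-1.52, 0.0, 0.0]), het=False, occ=1.0),
        _atom("CG", "C", "ASP", np.zeros(3), het=False, occ=1.0),
        _atom("OD1", "O", "ASP", od1, het=False, occ=1.0),
        _atom("OD2", "O", "ASP", od2, het=False, occ=1.0),
    ]
    if re_o2 is not None:
        re_pos = _circle_intersection(od2, re_o, od1, re_o2)
    elif mode == "monodentate":
        re_pos = od2 * (1.0 + re_o / CARBOXYLATE_CO)
    else:
        oo_half = CARBOXYLATE_CO * math.sin(half)
        if re_o <= oo_half:
            raise ValueError("re_o too short for a bidentate bridge")
        x0 = CARBOXYLATE_CO * math.cos(half) + math.sqrt(re_o**2 - oo_half**2)
        re_pos = np.array([x0, 0.0, 0.0])
    atoms.append(_atom("RE", "Re", "RE1", re_pos, occ=occupancy))
    return _place(atoms, center, orientation)


def _circle_intersection(p1, r1, p2, r2) -> np.ndarray:
    """In-plane (z = 0) intersection of two circles, the root further from
    the origin (i.e. away from the carboxylate carbon)."""
    d = float(np.linalg.norm(p2 - p1))
    if d > r1 + r2 or d < abs(r1 - r2):
        raise ValueError("requested Re–O distances are geometrically infeasible")
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h = math.sqrt(max(r1**2 - a**2, 0.0))
    mid = p1 + a * (p2 - p1) / d
    perp = np.array([-(p2 - p1)[1], (p2 - p1)[0], 0.0]) / d
    c1, c2 = mid + h * perp, mid - h * perp
    return c1 if np.linalg.norm(c1) >= np.linalg.norm(c2) else c2


def _as_rotation(orientation, rng: np.random.Generator | None = None) -> Rotation:
    if orientation is None:
        return Rotation.identity()
    if isinstance(orientation, Rotation):
        return orientation
    if isinstance(orientation, str):
        if orientation != "random":
            raise ValueError(f"unknown orientation {orientation!r}")
        if rng is None:
            raise ValueError("random orientation requires a generator")
        quat = rng.normal(size=4)
        return Rotation.from_quat(quat / np.linalg.norm(quat))
    arr = np.asarray(orientation, dtype=float)
    if arr.shape == (3, 3):
        return Rotation.from_matrix(arr)
    if arr.shape == (4,):
        return Rotation.from_quat(arr)
    raise ValueError("orientation must be None, 'random', a Rotation, 3x3 matrix or quaternion")


def _place(atoms: list[AtomRecord], center, orientation, rng=None) -> list[AtomRecord]:
    rot = _as_rotation(orientation, rng)
    center = np.asarray(center, dtype=float)
    return [a.moved(rot.apply(a.xyz) + center) for a in atoms]


_BUILDERS = {
    "cubane": build_cubane,
    "his_site": build_his_site,
    "carboxylate_site": build_carboxylate_site,
}


def _motif_truth(motif: MotifSpec, radii: RadiiTable) -> tuple[list[dict], list[int], list[dict]]:
    contacts, nuclearities, angles = [], [], []
    p = motif.params
    if motif.kind == "cubane":
        nuclearities.append(4)
    elif motif.kind == "his_site":
        re_n = p.get("re_n", 2.16)
        contacts.append(
            {"pair": ["Re", "N"], "atom": "NE2", "distance": re_n,
             "class": classify_contact(("Re", "N"), re_n, radii)}
        )
        if p.get("bromide"):
            re_br = p.get("re_br", RE_BR)
            contacts.append(
                {"pair": ["Re", "Br"], "atom": "BR", "distance": re_br,
                 "class": classify_contact(("Re", "Br"), re_br, radii)}
            )
        nuclearities.append(1)
    elif motif.kind == "carboxylate_site":
        re_o = p.get("re_o", 2.2)
        mode = p.get("mode", "monodentate")
        re_o2 = p.get("re_o2")
        contacts.append(
            {"pair": ["Re", "O"], "atom": "OD2", "distance": re_o,
             "class": classify_contact(("Re", "O"), re_o, radii)}
        )
        half = math.radians(CARBOXYLATE_OCO / 2.0)
        oo = 2.0 * CARBOXYLATE_CO * math.sin(half)
        if re_o2 is not None:
            d1 = re_o2
        elif mode == "bidentate":
            d1 = re_o
        else:
            # monodentate: law of cosines in the carboxylate triangle
            rc = CARBOXYLATE_CO + re_o
            d1 = math.sqrt(
                rc**2 + CARBOXYLATE_CO**2
                - 2 * rc * CARBOXYLATE_CO * math.cos(math.radians(CARBOXYLATE_OCO))
            )
        contacts.append(
            {"pair": ["Re", "O"], "atom": "OD1", "distance": round(d1, 4),
             "class": classify_contact(("Re", "O"), d1, radii)}
        )
        if mode == "bidentate" and re_o2 is None:
            angles.append(
                {"residue": "ASP", "atoms": ["OD1", "OD2"],
                 "angle_deg": round(math.degrees(2.0 * math.asin(oo / 2.0 / re_o)), 3)}
            )
        nuclearities.append(1)
    elif motif.kind == "lone_metal":
        nuclearities.append(1)
    return contacts, nuclearities, angles


def generate_structure(
    spec: SyntheticSpec, radii: RadiiTable | None = None
) -> tuple[StructureModel, GroundTruth]:
    """Assemble all motifs of a spec into one model plus its ground truth.

    Coordinates get seeded Gaussian noise of sd ``noise_sigma`` (none when
    zero, so noise-free output is independent of the seed unless a motif
    requests a random orientation).  Motif centers closer than
    ``min_separation`` raise unless ``allow_close`` is set.
    """
    radii = radii or RadiiTable()
    rng = np.random.default_rng(spec.seed)
    if not spec.allow_close:
        for (i, a), (j, b) in combinations(enumerate(spec.motifs), 2):
            d = float(np.linalg.norm(a.center - b.center))
            if d < spec.min_separation:
                raise ValueError(
                    f"motifs {i} and {j} are {d:.2f} Å apart "
                    f"(< {spec.min_separation} Å); set allow_close to override"
                )
    truth = GroundTruth(noise_sigma=spec.noise_sigma, seed=spec.seed)
    atoms: list[AtomRecord] = []
    serial = 0
    for idx, motif in enumerate(spec.motifs):
        resnum = motif.residue_number if motif.residue_number is not None else 100 + 10 * idx
        if motif.kind == "lone_metal":
            built = [_atom("RE", "Re", "RE1", np.zeros(3), occ=motif.occupancy)]
            built = _place(built, motif.center, motif.orientation, rng)
        elif motif.kind == "decoy_water":
            built = [_atom("O", "O", "HOH", np.zeros(3))]
            built = _place(built, motif.center, motif.orientation, rng)
        else:
            kwargs = dict(motif.params)
            built = _BUILDERS[motif.kind](
                center=motif.center, occupancy=motif.occupancy, **kwargs
            )
            if motif.orientation is not None:
                # builders place at center; rotate about the motif center
                rot = _as_rotation(motif.orientation, rng)
                built = [
                    a.moved(rot.apply(a.xyz - motif.center) + motif.center)
                    for a in built
                ]
        for a in built:
            serial += 1
            a.serial = serial
            a.chain = motif.chain
            a.residue_number = resnum
        atoms.extend(built)
        c, n, ang = _motif_truth(motif, radii)
        for entry in c:
            entry["motif"] = idx
            entry["chain"] = motif.chain
            entry["residue_number"] = resnum
        for entry in ang:
            entry["motif"] = idx
        truth.contacts.extend(c)
        truth.cluster_nuclearities.extend(n)
        truth.bite_angles.extend(ang)
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(len(atoms), 3))
        atoms = [a.moved(a.xyz + n) for a, n in zip(atoms, noise)]
    model = StructureModel(atoms=atoms, dpi=spec.dpi)
    return model, truth
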