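"""Structure ingestion: PDB chains -> centered atom clouds, plus synthetic fixtures.

A chain is represented by its atom coordinates (Å) and one-hot element types
over the order (C, H, O, N, S, Se). Chains containing any other element are
rejected as a value (not an exception) so callers can count and log them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .config import ELEMENTS

_ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}


class EmptyStructureError(ValueError):
    """Raised when a PDB text contains no usable ATOM records."""


class PDBLineError(ValueError):
    """Raised for an ATOM record that cannot be parsed; carries the line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class AtomCloud:
    """One protein chain as a point set of typed atoms."""

    coords: np.ndarray  # (M, 3) Å
    types: np.ndarray  # (M, 6) one-hot over ELEMENTS
    chain_id: str = ""
    source: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        types = np.asarray(self.types, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (M, 3), got {coords.shape}")
        if types.shape != (coords.shape[0], len(ELEMENTS)):
            raise ValueError(f"types must be (M, {len(ELEMENTS)}), got {types.shape}")
        if coords.shape[0] < 1:
            raise ValueError("atom cloud must contain at least one atom")
        if not np.allclose(types.sum(axis=1), 1.0):
            raise ValueError("each type row must be one-hot")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "types", types)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def elements(self) -> np.ndarray:
        """Element symbol per atom."""
        return np.array(ELEMENTS)[np.argmax(self.types, axis=1)]


@dataclass(frozen=True)
class ChainRejection:
    """Marker for a chain excluded by the element filter."""

    chain_id: str
    reason: str


def one_hot(element: str) -> np.ndarray:
    v = np.zeros(len(ELEMENTS))
    v[_ELEMENT_INDEX[element]] = 1.0
    return v


def _infer_element(atom_name: str, element_field: str) -> str:
    """Element symbol from the PDB element column, else from the atom name."""
    e = element_field.strip().capitalize()
    if e and e != "X":
        return e
    name = atom_name.strip()
    # strip leading digits (e.g. "1HB1"); two-letter elements are right-justified
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Se", "Fe", "Zn", "Mg", "Cl", "Br"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else ""


def _prescan_atom_lines(pdb_text: str) -> int:
    """Validate ATOM records line-by-line; returns the ATOM record count.

    gemmi is deliberately lenient, so malformed coordinate fields are caught
    here with the offending line number.
    """
    n_atom = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "ATOM  " or (rec.startswith("ATOM") and len(line) < 6):
            n_atom += 1
            if len(line) < 54:
                raise PDBLineError(lineno, "ATOM record shorter than 54 columns")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBLineError(lineno, f"unparseable {what} coordinate "
                                               f"{line[lo:hi]!r}") from None
    return n_atom


def parse_structure(pdb_text: str, source: str = "<text>") -> list[AtomCloud]:
    """Decompose PDB text into one uncentered AtomCloud per chain.

    Only ATOM records are used (HETATM and waters are ignored); alternate
    locations other than blank/'A' are dropped; only the first model of a
    multi-model file is read. Elements outside the supported set are kept
    here — :func:`filter_elements` decides the chain's fate.
    """
    if _prescan_atom_lines(pdb_text) == 0:
        raise EmptyStructureError(f"{source}: no ATOM records")
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise EmptyStructureError(f"{source}: no models")
    model = structure[0]  # first model only

    clouds = []
    for chain in model:
        coords, types, extra = [], [], []
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                elem = _infer_element(atom.name, atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                if elem in _ELEMENT_INDEX:
                    types.append(one_hot(elem))
                else:
                    # placeholder row; carried through for filter_elements
                    types.append(np.full(len(ELEMENTS), np.nan))
                    extra.append(elem)
        if coords:
            types_arr = np.array(types)
            if extra:
                cloud = _ForeignAtomCloud(
                    np.array(coords), types_arr, chain.name, source, tuple(extra)
                )
            else:
                cloud = AtomCloud(np.array(coords), types_arr, chain.name, source)
            clouds.append(cloud)
    if not clouds:
        raise EmptyStructureError(f"{source}: no polymer atoms in any chain")
    return clouds


class _ForeignAtomCloud(AtomCloud):
    """AtomCloud carrying atoms outside the supported element set.

    Exists only between parse and filter; the one-hot invariant is relaxed.
    """

    def __init__(self, coords, types, chain_id, source, foreign_elements):
        object.__setattr__(self, "coords", np.asarray(coords, dtype=np.float64))
        object.__setattr__(self, "types", np.asarray(types, dtype=np.float64))
        object.__setattr__(self, "chain_id", chain_id)
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "foreign_elements", foreign_elements)


def filter_elements(chain: AtomCloud) -> AtomCloud | ChainRejection:
    """Keep the chain iff every atom is in {C, H, O, N, S, Se}.

    Chains with any other element (metals, halides, ...) are returned as a
    :class:`ChainRejection` naming the first offending element.
    """
    if isinstance(chain, ChainRejection):
        return chain
    if isinstance(chain, _ForeignAtomCloud):
        return ChainRejection(chain.chain_id, chain.foreign_elements[0])
    return chain


def center_atoms(chain: AtomCloud) -> AtomCloud:
    """Subtract the mean coordinate; types and labels unchanged."""
    return replace(chain, coords=chain.coords - chain.coords.mean(axis=0))


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

#: atom-level element frequencies for synthetic chains (heavy atoms dominate,
#: as in deposited structures, which mostly lack hydrogens)
_SYNTH_ELEMENT_P = {"C": 0.58, "N": 0.17, "O": 0.20, "H": 0.03, "S": 0.015, "Se": 0.005}

_BACKBONE_STEP = 3.8  # Å, consecutive C-alpha spacing
_MIN_SELF_DIST = 3.0  # Å, self-avoidance radius of the backbone walk


def synth_chain(n_residues: int, seed: int) -> AtomCloud:
    """Generate a protein-like atom cloud: a self-avoiding 3.8 Å backbone walk
    with 1–4 pseudo side-chain atoms per residue and realistic element
    frequencies. Deterministic for a fixed seed; output is centered.

    A weak centripetal bias on the walk direction produces globular rather
    than extended shapes.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    rng = np.random.default_rng(seed)
    backbone = [np.zeros(3)]
    while len(backbone) < n_residues:
        pos = backbone[-1]
        for _ in range(200):
            d = rng.standard_normal(3) - 0.08 * pos
            d /= np.linalg.norm(d)
            cand = pos + _BACKBONE_STEP * d
            prev = np.array(backbone[:-1]) if len(backbone) > 1 else None
            if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) >= _MIN_SELF_DIST:
                backbone.append(cand)
                break
        else:  # walk trapped; restart from a jittered copy of the last point
            backbone.append(pos + _BACKBONE_STEP * _random_unit(rng))
    backbone = np.array(backbone)

    elements = list(_SYNTH_ELEMENT_P)
    probs = np.array([_SYNTH_ELEMENT_P[e] for e in elements])
    # backbone atoms occupy indices 0..n_residues-1, side-chain atoms follow
    coords = [b for b in backbone]
    types = [one_hot("C") for _ in backbone]  # backbone carbons
    for b in backbone:
        for _ in range(int(rng.integers(1, 5))):
            r = rng.uniform(0.8, 2.5)
            coords.append(b + r * _random_unit(rng))
            types.append(one_hot(elements[rng.choice(len(elements), p=probs)]))
    coords = np.array(coords)
    cloud = AtomCloud(coords, np.array(types), chain_id="SYN",
                      source=f"synth(n_residues={n_residues}, seed={seed})")
    return center_atoms(cloud)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_fixture(kind: str, **params) -> AtomCloud:
    """Analytic atom-cloud fixtures for geometry tests.

    kinds: ``single_atom`` (element), ``two_atoms`` (s, element),
    ``sphere_shell`` (radius, n, element), ``plane_slab`` (extent, spacing,
    element).
    """
    element = params.pop("element", "C")
    if kind == "single_atom":
        coords = np.zeros((1, 3))
    elif kind == "two_atoms":
        s = float(params.pop("s", 1.0))
        coords = np.array([[s, 0.0, 0.0], [-s, 0.0, 0.0]])
    elif kind == "sphere_shell":
        radius = float(params.pop("radius", 5.0))
        # dense enough that the soft-min SDF is negative everywhere inside
        # the shell (no spurious inner surface sheet)
        n = int(params.pop("n", max(64, int(12 * np.pi * radius**2))))
        coords = _fibonacci_sphere(n, radius)
    elif kind == "plane_slab":
        extent = float(params.pop("extent", 10.0))
        spacing = float(params.pop("spacing", 1.5))
        xs = np.arange(-extent, extent + 1e-9, spacing)
        gx, gy = np.meshgrid(xs, xs)
        coords = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=1)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if params:
        raise ValueError(f"unknown parameters for {kind}: {sorted(params)}")
    types = np.tile(one_hot(element), (coords.shape[0], 1))
    return AtomCloud(coords, types, chain_id=kind, source=f"fixture:{kind}")
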