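"""Reading and writing models, sequences, maps and map coefficients.

Coordinates are handled in orthogonal angstroms throughout; fractional
coordinates are obtained with the cell's standard fractionalization
matrix. Residue numbering is author numbering, as deposited.

Density can come from a real-space CCP4/MRC map or from 2mFo-DFc map
coefficients in an MTZ file; in the latter case the map is synthesized by
inverse Fourier transform on a grid with spacing <= d_min/3. All maps are
sigma-scaled (zero mean, unit variance over the unit cell) so downstream
features are scale free.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

from .alphabet import SEQUENCE_ALPHABET, three_to_one


class ParseError(ValueError):
    """Unreadable or ill-formed input file."""


class EmptyModelError(ValueError):
    """Structure contains no protein chain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSequence:
    """A reference (target) amino-acid sequence.

    residues is a one-letter string over the 20 standard letters plus 'X'.
    """

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, a in enumerate(self.residues, start=1):
            if a not in SEQUENCE_ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal character {a!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Residue:
    number: int
    icode: str
    type3: str
    type1: str = ""
    atoms: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.type1:
            self.type1 = three_to_one(self.type3)
        for name, pos in self.atoms.items():
            pos = np.asarray(pos, dtype=float)
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"residue {self.number}{self.icode}: non-finite {name}")
            self.atoms[name] = pos

    @property
    def key(self):
        return (self.number, self.icode)


@dataclass
class Chain:
    id: str
    residues: list
    is_protein: bool = True

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        for a, b in zip(keys, keys[1:]):
            if b <= a:
                raise ValueError(
                    f"chain {self.id}: residues not strictly increasing at {b}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    chains: list
    cell: tuple = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    spacegroup: str = "P 1"

    def __post_init__(self):
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0 or not all(0 < x < 180 for x in (al, be, ga)):
            raise ValueError(f"invalid unit cell {self.cell}")

    def protein_chains(self) -> list:
        return [c for c in self.chains if c.is_protein]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model")


@dataclass
class MapCoefficients:
    """Amplitude/phase Fourier coefficients (phases in degrees)."""

    hkl: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    labels: tuple
    cell: tuple

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if np.any(self.amplitude < 0):
            raise ValueError("negative structure-factor amplitude")
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate Miller indices")

    def d_min(self) -> float:
        frac = _frac_matrix(self.cell)
        s = self.hkl @ frac  # rows of frac are the reciprocal-cell vectors
        inv_d = np.linalg.norm(s, axis=1)
        inv_d = inv_d[inv_d > 0]
        if len(inv_d) == 0:
            raise ValueError("coefficients contain only (0,0,0)")
        return float(1.0 / inv_d.max())


def _frac_matrix(cell: tuple) -> np.ndarray:
    u = gemmi.UnitCell(*cell)
    return np.array(u.frac.mat.tolist(), dtype=float)


@dataclass
class DensityMap:
    """Periodic real-space density on a unit-cell grid.

    grid[i, j, k] samples fractional coordinate (i/na, j/nb, k/nc) along
    the a, b, c axes respectively.
    """

    grid: np.ndarray
    cell: tuple
    periodic: bool = True
    frac: np.ndarray = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("map grid must be 3-D with >= 2 points per axis")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("map contains non-finite values")
        if self.frac is None:
            self.frac = _frac_matrix(self.cell)

    def normalized(self) -> "DensityMap":
        g = self.grid
        sd = g.std()
        if sd == 0:
            raise ValueError("constant map cannot be sigma-scaled")
        return dataclasses.replace(self, grid=(g - g.mean()) / sd)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _convert_chain(gchain: "gemmi.Chain") -> Chain:
    residues = []
    seen = set()
    n_protein = 0
    for gres in gchain:
        key = (gres.seqid.num, gres.seqid.icode.strip())
        if key in seen:
            continue  # microheterogeneity: keep the first occurrence
        atoms = {}
        for at in gres:
            if at.altloc not in ("\x00", "", "A"):  # keep blank or 'A' altlocs
                continue
            if at.name not in atoms:
                atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
        info = gemmi.find_tabulated_residue(gres.name)
        if info is not None and info.is_amino_acid():
            n_protein += 1
        residues.append(Residue(number=key[0], icode=key[1], type3=gres.name, atoms=atoms))
        seen.add(key)
    residues.sort(key=lambda r: r.key)
    return Chain(id=gchain.name, residues=residues, is_protein=n_protein > 0)


def read_structure(path: str) -> StructureModel:
    """Read a PDB or mmCIF model (format detected by gemmi)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), merge_chain_parts=True)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models in file")
    st.setup_entities()
    chains = [_convert_chain(ch) for ch in st[0]]
    chains = [c for c in chains if len(c) > 0]
    model = StructureModel(
        chains=chains,
        cell=(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma),
        spacegroup=st.spacegroup_hm or "P 1",
    )
    if not model.protein_chains():
        raise EmptyModelError(f"{path}: no protein chains")
    return model


def write_structure(model: StructureModel, path: str) -> None:
    """Write a model as PDB (.pdb) or mmCIF (.cif/.mmcif)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell)
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    for chain in model.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.type3
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A" if chain.is_protein else "H"
            for name, pos in res.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.pos = gemmi.Position(*pos)
                at.element = gemmi.Element(name.strip("0123456789")[:1] or "C")
                at.occ = 1.0
                gres.add_atom(at)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    ext = os.path.splitext(path)[1].lower()
    if ext in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def model_sequence(chain: Chain):
    """One-letter sequence, residue numbers and a continuity flag.

    The flag is true iff the residue count matches the difference between
    flanking residue numbers and no insertion codes are present.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    seq = "".join(r.type1 for r in chain.residues)
    numbers = [r.number for r in chain.residues]
    continuous = (
        all(r.icode == "" for r in chain.residues)
        and numbers[-1] - numbers[0] + 1 == len(numbers)
    )
    return seq, numbers, continuous


def continuous_runs(chain: Chain) -> list:
    """Maximal runs of consecutively numbered, icode-free residues.

    Returns (start_index, end_index) pairs, end inclusive.
    """
    runs = []
    start = None
    for i, res in enumerate(chain.residues):
        if res.icode != "":
            if start is not None:
                runs.append((start, i - 1))
                start = None
            continue
        if start is None:
            start = i
        elif res.number != chain.residues[i - 1].number + 1 or chain.residues[i - 1].icode != "":
            runs.append((start, i - 1))
            start = i
    if start is not None:
        runs.append((start, len(chain) - 1))
    return runs


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequences(path: str) -> list:
    """Read target sequences from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    out = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        seq = seq.rstrip("*")
        try:
            out.append(TargetSequence(id=rec.id, residues=seq))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return out


def write_sequences(sequences: Iterable[TargetSequence], path: str) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# maps and coefficients
# ---------------------------------------------------------------------------

#: auto-detected 2mFo-DFc column dialects, tried in order
DEFAULT_MTZ_LABELS = (("FWT", "PHWT"), ("2FOFCWT", "PH2FOFCWT"))


def read_map_coefficients(path: str, labels: Optional[Sequence[str]] = None) -> MapCoefficients:
    """Read amplitude/phase coefficients from an MTZ file."""
    try:
        mtz = gemmi.read_mtz_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    available = [c.label for c in mtz.columns]
    if labels is not None:
        pairs = [tuple(labels)]
    else:
        pairs = list(DEFAULT_MTZ_LABELS)
    chosen = None
    for f_lab, phi_lab in pairs:
        if f_lab in available and phi_lab in available:
            chosen = (f_lab, phi_lab)
            break
    if chosen is None:
        raise ParseError(
            f"{path}: no amplitude/phase columns among {pairs}; available: {available}"
        )
    arr = np.array(mtz, copy=True)
    cols = {c.label: i for i, c in enumerate(mtz.columns)}
    hkl = arr[:, [cols["H"], cols["K"], cols["L"]]].astype(np.int64)
    amp = arr[:, cols[chosen[0]]].astype(float)
    phi = arr[:, cols[chosen[1]]].astype(float)
    ok = np.isfinite(amp) & np.isfinite(phi)
    cell = (mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    return MapCoefficients(hkl=hkl[ok], amplitude=amp[ok], phase=phi[ok], labels=chosen, cell=cell)


def _grid_size(n_min: int) -> int:
    """Smallest even, FFT-friendly (2,3,5-smooth) size >= n_min."""
    n = max(int(n_min), 2)
    while True:
        if n % 2 == 0:
            m = n
            for p in (2, 3, 5):
                while m % p == 0:
                    m //= p
            if m == 1:
                return n
        n += 1


def synthesize_map(coeffs: MapCoefficients, grid_spacing: Optional[float] = None,
                   normalize: bool = True) -> DensityMap:
    """Inverse Fourier transform of map coefficients onto a unit-cell grid.

    rho(x) ~ sum_h F(h) exp(-2 pi i h.x); spacing defaults to d_min/3.
    """
    spacing = grid_spacing if grid_spacing is not None else coeffs.d_min() / 3.0
    a, b, c = coeffs.cell[:3]
    hmax = np.abs(coeffs.hkl).max(axis=0)
    dims = tuple(
        _grid_size(max(math.ceil(length / spacing), 2 * int(h) + 2))
        for length, h in zip((a, b, c), hmax)
    )
    C = np.zeros(dims, dtype=complex)
    F = coeffs.amplitude * np.exp(1j * np.deg2rad(coeffs.phase))
    idx = coeffs.hkl % np.array(dims)
    C[idx[:, 0], idx[:, 1], idx[:, 2]] = F
    # Friedel mates for hemisphere data (do not overwrite explicit entries)
    neg = (-coeffs.hkl) % np.array(dims)
    for (i, j, k), f in zip(neg, F):
        if C[i, j, k] == 0 and (i, j, k) != (0, 0, 0):
            C[i, j, k] = np.conj(f)
    density = np.fft.fftn(C).real
    dmap = DensityMap(grid=density, cell=coeffs.cell)
    return dmap.normalized() if normalize else dmap


def read_map_or_coefficients(path: str, labels: Optional[Sequence[str]] = None) -> DensityMap:
    """Read a CCP4/MRC map, or synthesize a map from MTZ coefficients.

    The returned map is sigma-scaled in both cases.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mtz":
        return synthesize_map(read_map_coefficients(path, labels))
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: not a CCP4/MRC map: {exc}") from exc
    m.setup(float("nan"))
    grid = np.array(m.grid.array, dtype=float)
    if np.isnan(grid).any():
        raise ParseError(f"{path}: map does not cover the unit cell")
    u = m.grid.unit_cell
    dmap = DensityMap(grid=grid, cell=(u.a, u.b, u.c, u.alpha, u.beta, u.gamma))
    return dmap.normalized()


def write_map(dmap: DensityMap, path: str) -> None:
    g = gemmi.FloatGrid(*dmap.grid.shape)
    g.set_unit_cell(gemmi.UnitCell(*dmap.cell))
    np.asarray(g.array)[:] = dmap.grid.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def interpolate(dmap: DensityMap, position) -> np.ndarray:
    """Trilinear interpolation at orthogonal-angstrom position(s).

    Accepts a single (3,) position or an (n, 3) array; periodic wrapping,
    exact at grid nodes.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    frac = pos @ dmap.frac.T
    if not dmap.periodic:
        if np.any(frac < 0) or np.any(frac >= 1):
            raise ValueError("position outside a non-periodic map")
    dims = np.array(dmap.grid.shape)
    g = frac * dims
    i0 = np.floor(g).astype(np.int64)
    w = g - i0
    out = np.zeros(len(pos))
    for corner in range(8):
        bits = np.array([(corner >> s) & 1 for s in (2, 1, 0)])
        idx = (i0 + bits) % dims
        weight = np.prod(np.where(bits, w, 1.0 - w), axis=1)
        out += weight * dmap.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out[0] if np.asarray(position).ndim == 1 else out
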