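"""Ground-truth benchmark generation and detector scoring.

The generator emulates the statistical behaviour of a residue-type
classifier with a tunable accuracy ``alpha``: for each residue a
predicted label is drawn (the true type with probability alpha,
otherwise a draw from a confusion kernel) and the emitted probability
row places mass alpha on that label, so the row argmax equals the truth
with frequency alpha. Register shifts, indexing issues, numbering gaps,
mismatches and UNK residues are injected with exact bookkeeping, and
:func:`evaluate` scores detector output against the injected truth.

Everything is deterministic under a fixed seed. Map-level synthesis
(:func:`gen_structure`, :func:`gen_density_map`) produces toy models
with Gaussian-atom density for exercising the density classifier;
crystallographic noise, model bias and resolution effects are *not*
simulated -- alpha is an abstract accuracy knob.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA1, AA_INDEX, N_TYPES, ONE_TO_THREE
from .register_scanner import IssueRegion
from .residue_classifier import SIDE_CHAIN_DISTANCES, ResidueProfile, pseudo_cb
from .structure_io import (Chain, DensityMap, Residue, StructureModel,
                           TargetSequence, _frac_matrix)

#: similarity groups used by the similarity-weighted confusion kernel
_SIMILAR_GROUPS = (("D", "N"), ("E", "Q"), ("V", "T", "I"), ("F", "Y"))
_SIMILAR_BOOST = 5.0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def confusion_kernel(kind: str = "uniform") -> np.ndarray:
    """(20, 20) row-stochastic kernel with zero diagonal.

    'uniform' spreads the off-truth mass evenly; 'similar' up-weights
    confusions within chemically similar groups (D/N, E/Q, V/T/I, F/Y).
    """
    K = np.ones((N_TYPES, N_TYPES))
    if kind == "similar":
        for group in _SIMILAR_GROUPS:
            idx = [AA_INDEX[a] for a in group]
            for i in idx:
                for j in idx:
                    K[i, j] = _SIMILAR_BOOST
    elif kind != "uniform":
        raise ValueError(f"unknown confusion kernel {kind!r}")
    np.fill_diagonal(K, 0.0)
    return K / K.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Benchmark recipe. Positions are 1-based ordinals along the chain.

    shifts: (start, end, offset) register shifts -- the density (truth)
      at ordinal i is target position i+offset while the model still
      claims position i;
    indexing_shifts: like shifts but the claimed identities follow the
      density (identities right, numbering wrong);
    numbering_gaps: (position, gap) -- residue numbers jump by ``gap``
      after ``position``, identities unchanged (a properly numbered
      unmodelled loop);
    mismatches: (position, wrong_type) claimed-type point errors; 'X'
      injects a UNK residue.
    """

    chain_length: int
    accuracy: float = 0.9
    confusion: str = "uniform"
    shifts: tuple = ()
    indexing_shifts: tuple = ()
    numbering_gaps: tuple = ()
    mismatches: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.accuracy <= 1:
            raise ValueError("accuracy must be in (0, 1]")
        spans = sorted([(s, e) for s, e, _ in tuple(self.shifts) + tuple(self.indexing_shifts)])
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("shift regions must not overlap")
        for s, e, off in tuple(self.shifts) + tuple(self.indexing_shifts):
            if not (1 <= s <= e <= self.chain_length) or off == 0:
                raise ValueError(f"invalid shift region ({s},{e},{off})")


@dataclass
class GroundTruth:
    """What each residue's density really represents (1-based target
    positions) plus the injected issue regions in author numbering."""

    chain_id: str
    seq_id: str
    residue_keys: list
    true_types: str
    true_positions: list
    regions: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_sequence(length: int, background: Optional[np.ndarray] = None,
                 seed=0, seq_id: str = "target") -> TargetSequence:
    """I.i.d. random target sequence; deterministic given the seed."""
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    rng = _rng(seed)
    bg = np.full(N_TYPES, 1.0 / N_TYPES) if background is None else np.asarray(background)
    letters = rng.choice(list(AA1), size=length, p=bg / bg.sum())
    return TargetSequence(id=seq_id, residues="".join(letters))


def inject_errors(spec: SyntheticSpec, target: TargetSequence,
                  chain_id: str = "A") -> tuple:
    """Build a claimed chain and its ground truth from a spec.

    Sign convention: positive offset means the true sequence position
    exceeds the claimed one.
    """
    n = spec.chain_length
    if n > len(target):
        raise ValueError("chain longer than target sequence")
    true_pos = list(range(1, n + 1))
    claimed = [target.residues[i - 1] for i in range(1, n + 1)]
    regions_ord = []  # (category, start_ordinal, end_ordinal, offset)
    for s, e, off in spec.shifts:
        for i in range(s, e + 1):
            p = i + off
            if not 1 <= p <= len(target):
                raise ValueError(f"shift ({s},{e},{off}) leaves the target")
            true_pos[i - 1] = p
        regions_ord.append(("register_shift", s, e, off))
    for s, e, off in spec.indexing_shifts:
        for i in range(s, e + 1):
            p = i + off
            if not 1 <= p <= len(target):
                raise ValueError(f"indexing shift ({s},{e},{off}) leaves the target")
            true_pos[i - 1] = p
            claimed[i - 1] = target.residues[p - 1]
        regions_ord.append(("indexing_issue", s, e, off))
    for pos, wrong in spec.mismatches:
        if not 1 <= pos <= n:
            raise ValueError(f"mismatch position {pos} outside chain")
        claimed[pos - 1] = wrong
        regions_ord.append(("sequence_mismatch", pos, pos, None))
    numbers = list(range(1, n + 1))
    for pos, gap in spec.numbering_gaps:
        for j in range(pos, n):  # ordinals strictly after `pos`
            numbers[j] += gap
    resnum = {i + 1: numbers[i] for i in range(n)}
    residues = [
        Residue(number=numbers[i], icode="",
                type3=ONE_TO_THREE.get(claimed[i], "UNK"))
        for i in range(n)
    ]
    chain = Chain(id=chain_id, residues=residues)
    true_types = "".join(target.residues[p - 1] for p in true_pos)
    regions = [
        IssueRegion(chain_id, cat, resnum[s], resnum[e], offset=off)
        for cat, s, e, off in regions_ord
    ]
    truth = GroundTruth(chain_id=chain_id, seq_id=target.id,
                        residue_keys=[r.key for r in residues],
                        true_types=true_types, true_positions=true_pos,
                        regions=regions)
    return chain, truth


def gen_profile(truth: GroundTruth, alpha: float, confusion: str = "uniform",
                seed=0, jitter: float = 0.3) -> ResidueProfile:
    """Confusion-noise probability profile for a ground truth.

    A predicted label is drawn per residue (truth w.p. alpha, else from
    the confusion kernel); the row places mass alpha on the label and
    spreads 1-alpha over the other types by the kernel. Rows are then
    multiplied by log-normal noise of scale ``jitter`` and renormalized:
    real classifier posteriors vary continuously from residue to
    residue, and without jitter every row would share one value multiset,
    collapsing window score distributions onto a coarse lattice no
    actual classifier produces. jitter=0 gives the clean two-level rows.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = _rng(seed)
    K = confusion_kernel(confusion)
    n = len(truth.true_types)
    true_idx = np.array([AA_INDEX[a] for a in truth.true_types])
    labels = true_idx.copy()
    if alpha < 1:
        flip = rng.random(n) >= alpha
        for i in np.flatnonzero(flip):
            labels[i] = rng.choice(N_TYPES, p=K[true_idx[i]])
    rows = (1.0 - alpha) * K[labels]
    rows[np.arange(n), labels] += alpha
    if jitter > 0:
        rows = rows * np.exp(jitter * rng.standard_normal(rows.shape))
        rows /= rows.sum(axis=1, keepdims=True)
    rows /= rows.sum(axis=1, keepdims=True)
    return ResidueProfile(chain_id=truth.chain_id, residue_keys=list(truth.residue_keys),
                          probs=rows)


def gen_benchmark(chain_length: int = 300, alpha: float = 0.9,
                  shifts: tuple = (), indexing_shifts: tuple = (),
                  numbering_gaps: tuple = (), mismatches: tuple = (),
                  confusion: str = "uniform", n_decoys: int = 0,
                  target_length: Optional[int] = None, seed: int = 0) -> dict:
    """One-call benchmark: target(s), claimed chain, truth and profile."""
    rng = _rng(seed)
    need = chain_length + max([off for _, _, off in tuple(shifts) + tuple(indexing_shifts)] + [0])
    tlen = target_length if target_length is not None else max(chain_length, need)
    target = gen_sequence(tlen, seed=rng, seq_id="target")
    sequences = [target] + [
        gen_sequence(tlen, seed=rng, seq_id=f"decoy{i+1}") for i in range(n_decoys)
    ]
    spec = SyntheticSpec(chain_length=chain_length, accuracy=alpha, confusion=confusion,
                         shifts=tuple(shifts), indexing_shifts=tuple(indexing_shifts),
                         numbering_gaps=tuple(numbering_gaps), mismatches=tuple(mismatches))
    chain, truth = inject_errors(spec, target)
    profile = gen_profile(truth, alpha, confusion, seed=rng)
    return {"sequences": sequences, "target": target, "chain": chain,
            "truth": truth, "profile": profile, "spec": spec}


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    chain_id: str
    start_index: int
    length: int
    start: int  # author residue numbers
    end: int


def sample_fragments(model: StructureModel, n_per_length: int = 3,
                     lengths: Sequence[int] = (10, 20), seed=0) -> list:
    """Random continuous test fragments from each protein chain.

    Up to ``n_per_length`` start positions per chain and length are drawn
    uniformly without replacement; sampled fragments containing UNK
    residues, insertion codes, or whose residue count does not match the
    difference between flanking residue numbers are rejected, which may
    reduce the returned count below the requested one.
    """
    rng = _rng(seed)
    fragments = []
    for chain in model.protein_chains():
        for L in lengths:
            n_starts = len(chain) - L + 1
            if n_starts <= 0:
                continue
            k = min(n_per_length, n_starts)
            starts = rng.choice(n_starts, size=k, replace=False)
            for s in sorted(int(x) for x in starts):
                frag = chain.residues[s : s + L]
                if any(r.type1 == "X" for r in frag):
                    continue
                if any(r.icode != "" for r in frag):
                    continue
                if frag[-1].number - frag[0].number != L - 1:
                    continue
                fragments.append(Fragment(chain.id, s, L, frag[0].number, frag[-1].number))
    return fragments


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _overlap(a: IssueRegion, b: IssueRegion) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def evaluate(detected: Sequence[IssueRegion], truth) -> dict:
    """Region-level recall/precision and boundary-error summary.

    A detected region matches a true region iff the categories agree,
    the offsets agree, and the overlap covers at least half of the true
    span. Boundary error per matched pair is the larger of the two
    endpoint discrepancies.
    """
    true_regions = truth.regions if isinstance(truth, GroundTruth) else list(truth)
    matched = []
    used = set()
    for t in true_regions:
        span = t.end - t.start + 1
        best_j, best_ov = None, 0
        for j, d in enumerate(detected):
            if j in used or d.category != t.category or d.offset != t.offset:
                continue
            ov = _overlap(d, t)
            if ov >= 0.5 * span and ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            used.add(best_j)
            d = detected[best_j]
            matched.append((t, d, max(abs(d.start - t.start), abs(d.end - t.end))))
    errors = [m[2] for m in matched]
    n_true = len(true_regions)
    n_det = len(detected)
    return {
        "n_true": n_true,
        "n_detected": n_det,
        "n_matched": len(matched),
        "recall": len(matched) / n_true if n_true else 1.0,
        "precision": len(matched) / n_det if n_det else 1.0,
        "boundary_errors": errors,
        "median_boundary_error": float(np.median(errors)) if errors else float("nan"),
        "p90_boundary_error": float(np.percentile(errors, 90)) if errors else float("nan"),
        "matches": matched,
    }


# ---------------------------------------------------------------------------
# toy structures and maps
# ---------------------------------------------------------------------------

_GOLDEN = math.pi * (3.0 - math.sqrt(5.0))


def gen_structure(sequence: str, chain_id: str = "A", padding: float = 12.0) -> StructureModel:
    """Extended-chain toy model with pseudo side chains.

    Backbone atoms follow an idealized extended trace (3.5 A per
    residue); side-chain pseudo-atoms sit at each type's ideal distances
    from CB, fanned out deterministically away from the backbone, with
    side chains alternating sides as in a beta strand.
    """
    n = len(sequence)
    chains = []
    residues = []
    x0 = padding
    y0 = z0 = 0.0  # shifted into the box below
    for i, aa in enumerate(sequence):
        sgn = 1.0 if i % 2 == 0 else -1.0
        ca = np.array([x0 + 3.5 * i, 0.0, 0.0])
        nat = ca + np.array([-1.20, -0.80 * sgn, 0.25])
        cat = ca + np.array([1.20, -0.80 * sgn, -0.25])
        oat = cat + np.array([0.45, -1.05 * sgn, 0.0])
        atoms = {"N": nat, "CA": ca, "C": cat, "O": oat}
        distances = SIDE_CHAIN_DISTANCES.get(aa, [])
        if distances:
            cb = pseudo_cb(nat, ca, cat)
            u = cb - ca
            u /= np.linalg.norm(u)
            p1 = np.cross(u, [1.0, 0.0, 0.0])
            if np.linalg.norm(p1) < 1e-6:
                p1 = np.cross(u, [0.0, 1.0, 0.0])
            p1 /= np.linalg.norm(p1)
            p2 = np.cross(u, p1)
            atoms["CB"] = cb
            for k, d in enumerate(distances[1:], start=1):
                phi = k * _GOLDEN
                tilt = math.radians(25.0)
                direction = (math.cos(tilt) * u
                             + math.sin(tilt) * (math.cos(phi) * p1 + math.sin(phi) * p2))
                atoms[f"C{k}"] = cb + d * direction
        residues.append(Residue(number=i + 1, icode="",
                                type3=ONE_TO_THREE.get(aa, "UNK"), atoms=atoms))
    coords = np.array([p for r in residues for p in r.atoms.values()])
    lo = coords.min(axis=0) - padding
    span = coords.max(axis=0) - coords.min(axis=0) + 2 * padding
    for r in residues:
        for name in r.atoms:
            r.atoms[name] = r.atoms[name] - lo
    chains.append(Chain(id=chain_id, residues=residues))
    cell = (float(span[0]), float(span[1]), float(span[2]), 90.0, 90.0, 90.0)
    return StructureModel(chains=chains, cell=cell, spacegroup="P 1")


def gen_density_map(model: StructureModel, spacing: float = 0.6,
                    sigma: float = 1.0, normalize: bool = True) -> DensityMap:
    """Direct-space Gaussian-atom density for a model (periodic, P1).

    Only orthorhombic cells are supported (all generated toy models use
    them; the displacement arithmetic below assumes orthogonal axes).
    """
    if tuple(model.cell[3:]) != (90.0, 90.0, 90.0):
        raise ValueError("gen_density_map requires an orthorhombic cell")
    a, b, c = model.cell[:3]
    dims = tuple(max(2, 2 * int(math.ceil(length / spacing / 2))) for length in (a, b, c))
    grid = np.zeros(dims)
    frac = _frac_matrix(model.cell)
    orth = np.linalg.inv(frac)
    step = np.array([a, b, c]) / np.array(dims)
    rad = np.ceil(4.0 * sigma / step).astype(int)
    offs = [np.arange(-r, r + 1) for r in rad]
    for chain in model.chains:
        for res in chain.residues:
            for pos in res.atoms.values():
                fr = frac @ pos
                center = np.round(fr * dims).astype(int)
                idx = [(center[d] + offs[d]) % dims[d] for d in range(3)]
                fr_pts = [(center[d] + offs[d]) / dims[d] for d in range(3)]
                # periodic displacement in fractional space
                d0 = fr_pts[0] - fr[0]
                d1 = fr_pts[1] - fr[1]
                d2 = fr_pts[2] - fr[2]
                dx = (orth[0, 0] * d0)[:, None, None] + np.zeros((1, len(d1), len(d2)))
                dy = (orth[1, 1] * d1)[None, :, None] + np.zeros((len(d0), 1, len(d2)))
                dz = (orth[2, 2] * d2)[None, None, :] + np.zeros((len(d0), len(d1), 1))
                r2 = dx * dx + dy * dy + dz * dz
                grid[np.ix_(idx[0], idx[1], idx[2])] += np.exp(-r2 / (2 * sigma * sigma))
    dmap = DensityMap(grid=grid, cell=model.cell)
    return dmap.normalized() if normalize else dmap


# ---------------------------------------------------------------------------
# on-disk benchmark bundles
# ---------------------------------------------------------------------------

def write_claimed_table(chain: Chain, path: str) -> None:
    """Claimed-assignment table: chain, resnum, icode, type3 (TSV)."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\ttype3\n")
        for r in chain.residues:
            fh.write(f"{chain.id}\t{r.number}\t{r.icode or '.'}\t{r.type3}\n")


def read_claimed_table(path: str) -> StructureModel:
    """Read a claimed-assignment table as an atomless model."""
    chains = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["chain", "resnum", "icode", "type3"]:
            raise ValueError(f"{path}: not a claimed-assignment table")
        for line in fh:
            cid, num, icode, type3 = line.rstrip("\n").split("\t")
            chains.setdefault(cid, []).append(
                Residue(number=int(num), icode="" if icode == "." else icode, type3=type3)
            )
    if not chains:
        raise ValueError(f"{path}: empty claimed-assignment table")
    span = 10.0 * max(len(v) for v in chains.values())
    return StructureModel(chains=[Chain(id=k, residues=v) for k, v in chains.items()],
                          cell=(span, span, span, 90.0, 90.0, 90.0))


def write_bundle(directory: str, bench: dict) -> dict:
    """Write a generated benchmark as plain-text files; returns the paths."""
    from .residue_classifier import write_profile_table
    from .structure_io import write_sequences

    os.makedirs(directory, exist_ok=True)
    paths = {
        "fasta": os.path.join(directory, "targets.fasta"),
        "profile": os.path.join(directory, "profile.tsv"),
        "claimed": os.path.join(directory, "claimed.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_sequences(bench["sequences"], paths["fasta"])
    write_profile_table(bench["profile"], paths["profile"])
    write_claimed_table(bench["chain"], paths["claimed"])
    truth = bench["truth"]
    with open(paths["truth"], "w") as fh:
        json.dump({
            "chain_id": truth.chain_id,
            "seq_id": truth.seq_id,
            "residue_keys": [[n, ic] for n, ic in truth.residue_keys],
            "true_types": truth.true_types,
            "true_positions": truth.true_positions,
            "regions": [
                {"chain_id": r.chain_id, "category": r.category, "start": r.start,
                 "end": r.end, "offset": r.offset}
                for r in truth.regions
            ],
        }, fh, indent=1, sort_keys=True)
    return paths


def read_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        chain_id=d["chain_id"], seq_id=d["seq_id"],
        residue_keys=[(int(n), ic) for n, ic in d["residue_keys"]],
        true_types=d["true_types"], true_positions=d["true_positions"],
        regions=[IssueRegion(r["chain_id"], r["category"], r["start"], r["end"],
                             offset=r["offset"]) for r in d["regions"]],
    )
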