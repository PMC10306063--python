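"""Per-residue residue-type probability profiles from a model and a map.

The profile contract is the module's point: any callable mapping
``(model, map, chain, residue)`` to a valid 20-class probability row can
stand behind :func:`extract_profile` (e.g. an external learned
classifier, or a precomputed table read with :func:`read_profile_table`).

The built-in baseline is a transparent geometric classifier: mean
sigma-scaled density is sampled in radial shells around the side-chain
anchor (CB, or a pseudo-CB for glycine and incomplete residues), a local
backbone baseline is subtracted, and the shell profile is matched by
least squares against per-type templates derived from ideal side-chain
geometry (Gaussian-smeared expected occupancy of the side-chain heavy
atoms per shell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .alphabet import AA1, AA_INDEX, N_TYPES
from .structure_io import Chain, DensityMap, Residue, StructureModel, interpolate


class FeatureError(ValueError):
    """Residue lacks the backbone atoms needed for shell features."""


#: ideal side-chain heavy-atom distances from CB (angstroms), per type.
#: Atom counts per type: G=0, A=1, S=2, C=2, T=3, V=3, P=3, N=4, D=4, I=4,
#: L=4, M=4, E=5, Q=5, K=5, H=6, R=7, F=7, Y=8, W=10. Distances beyond the
#: outermost shell edge are clipped into the last shell.
SIDE_CHAIN_DISTANCES = {
    "G": [],
    "A": [0.0],
    "S": [0.0, 1.42],
    "C": [0.0, 1.81],
    "T": [0.0, 1.43, 1.53],
    "V": [0.0, 1.53, 1.53],
    "P": [0.0, 1.50, 2.40],
    "N": [0.0, 1.53, 2.46, 2.44],
    "D": [0.0, 1.53, 2.46, 2.44],
    "I": [0.0, 1.53, 1.53, 2.56],
    "L": [0.0, 1.53, 2.54, 2.54],
    "M": [0.0, 1.53, 2.81, 4.22],
    "E": [0.0, 1.53, 2.56, 3.67, 3.70],
    "Q": [0.0, 1.53, 2.56, 3.67, 3.70],
    "K": [0.0, 1.53, 2.56, 3.92, 4.96],
    "H": [0.0, 1.53, 2.47, 2.51, 3.60, 3.62],
    "R": [0.0, 1.53, 2.56, 3.90, 4.82, 5.40, 5.40],
    "F": [0.0, 1.53, 2.54, 2.54, 3.82, 3.82, 4.36],
    "Y": [0.0, 1.53, 2.54, 2.54, 3.82, 3.82, 4.36, 5.40],
    "W": [0.0, 1.53, 2.48, 2.52, 3.64, 3.70, 3.80, 4.80, 4.90, 5.30],
}


@dataclass
class ClassifierConfig:
    shell_edges: tuple = (0.0, 1.5, 2.5, 3.5, 4.5, 5.5)
    samples_per_shell: int = 48
    softmax_temperature: float = 0.25
    probability_floor: float = 1e-4
    atom_sigma: float = 1.0  # Gaussian width (A) used for the template smearing
    contact_radius: float = 3.0  # mask sample points this close to other chains
    mask_radius: float = 1.2  # mask points this close to non-side-chain atoms

    def __post_init__(self):
        edges = np.asarray(self.shell_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("shell edges must be strictly increasing")
        if not 0 < self.probability_floor < 1.0 / N_TYPES:
            raise ValueError("probability_floor must be in (0, 1/20)")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")

    @property
    def n_shells(self) -> int:
        return len(self.shell_edges) - 1


@dataclass
class ResidueProfile:
    """Per-residue 20-class probability rows for one chain.

    Rows are ordered as the residues in the chain; columns follow the
    fixed alphabetical one-letter order. ``flagged`` holds indices of
    residues whose classification failed (their rows are uniform).
    """

    chain_id: str
    residue_keys: list
    probs: np.ndarray
    flagged: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.residue_keys), N_TYPES):
            raise ValueError("probs must be (n_residues, 20)")
        if np.any(self.probs < 0):
            raise ValueError("negative probability in profile")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("profile rows must sum to 1")

    def __len__(self) -> int:
        return len(self.residue_keys)


# ---------------------------------------------------------------------------
# shell geometry
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-angle lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * (math.pi * (3.0 - math.sqrt(5.0)))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shell_sample_points(anchor: np.ndarray, config: ClassifierConfig) -> list:
    """Fixed sample-point sets, one (n, 3) array per radial shell."""
    out = []
    edges = config.shell_edges
    for k in range(config.n_shells):
        radius = 0.5 * (edges[k] + edges[k + 1])
        if radius == 0:
            out.append(anchor[None, :])
        else:
            out.append(anchor + radius * fibonacci_sphere(config.samples_per_shell))
    return out


def pseudo_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB position from backbone N/CA/C and ideal tetrahedral geometry."""
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv + ca


def _anchor(residue: Residue) -> np.ndarray:
    if "CB" in residue.atoms:
        return residue.atoms["CB"]
    for name in ("N", "CA", "C"):
        if name not in residue.atoms:
            raise FeatureError(
                f"residue {residue.number}{residue.icode}: missing backbone atom {name}"
            )
    return pseudo_cb(residue.atoms["N"], residue.atoms["CA"], residue.atoms["C"])


_BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT")


def _foreign_trees(model: StructureModel, chain_id: str):
    """KD-trees of atoms that are never part of a residue's own side chain.

    Returns (other_chain_tree, own_chain_coords, own_chain_owner) where
    owner[i] is the index of the residue an own-chain atom belongs to
    (side-chain atoms included: a neighbour's side chain is contamination
    for this residue even though its type label may be wrong -- its
    coordinates still sit in real density).
    """
    other = [
        pos
        for ch in model.chains
        if ch.id != chain_id
        for res in ch.residues
        for pos in res.atoms.values()
    ]
    other_tree = cKDTree(np.array(other)) if other else None
    own_coords, owner, backbone = [], [], []
    chain = model.get_chain(chain_id)
    for i, res in enumerate(chain.residues):
        for name, pos in res.atoms.items():
            own_coords.append(pos)
            owner.append(i)
            backbone.append(name in _BACKBONE_NAMES)
    return other_tree, np.array(own_coords), np.array(owner), np.array(backbone)


def _gaussian_model_density(points: np.ndarray, coords: np.ndarray,
                            sigma: float) -> np.ndarray:
    """Sum of unit Gaussians centred at ``coords``, evaluated at points."""
    if coords is None or len(coords) == 0:
        return np.zeros(len(points))
    d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma * sigma)).sum(axis=1)


def shell_features(model: StructureModel, dmap: DensityMap, residue: Residue,
                   config: Optional[ClassifierConfig] = None,
                   neighbor_tree: Optional[cKDTree] = None,
                   foreign_tree: Optional[cKDTree] = None,
                   foreign_coords: Optional[np.ndarray] = None) -> np.ndarray:
    """Mean side-chain density per radial shell around the anchor.

    The local baseline is the Gaussian density computed from every atom
    that is not part of this residue's side chain (its own backbone and
    all neighbouring residues), scaled to the map via the mean map level
    at the residue's backbone atoms; it is subtracted point-by-point
    before averaging (omit-style difference density), so feature k
    estimates the side chain's own contribution to shell k. Sample
    points within ``contact_radius`` of another chain's atoms or within
    ``mask_radius`` of a non-side-chain atom are masked out, and the
    shell mean is multiplied by the surviving-point fraction so it stays
    comparable to a full spherical average. Deterministic given the
    configuration.
    """
    config = config or ClassifierConfig()
    anchor = _anchor(residue)
    backbone = [residue.atoms[n] for n in ("N", "CA", "C", "O") if n in residue.atoms]
    if not backbone:
        raise FeatureError(f"residue {residue.number}{residue.icode}: no backbone atoms")
    backbone = np.array(backbone)
    base_map = float(np.mean(interpolate(dmap, backbone)))
    base_model = float(np.mean(_gaussian_model_density(backbone, foreign_coords,
                                                       config.atom_sigma)))
    alpha = base_map / base_model if base_model > 1e-9 else 0.0
    features = np.zeros(config.n_shells)
    for k, points in enumerate(shell_sample_points(anchor, config)):
        n_total = len(points)
        if neighbor_tree is not None and len(points):
            dist, _ = neighbor_tree.query(points, k=1)
            points = points[dist >= config.contact_radius]
        if foreign_tree is not None and len(points):
            dist, _ = foreign_tree.query(points, k=1)
            points = points[dist >= config.mask_radius]
        if len(points):
            vals = interpolate(dmap, points) - alpha * _gaussian_model_density(
                points, foreign_coords, config.atom_sigma)
            features[k] = (len(points) / n_total) * float(np.mean(vals))
    return features


# ---------------------------------------------------------------------------
# templates and classification
# ---------------------------------------------------------------------------

def _gaussian_shell_average(d: float, r: float, sigma: float) -> float:
    """Average over a sphere of radius r of a unit Gaussian centred at
    distance d from the sphere's centre."""
    if r == 0:
        return math.exp(-(d * d) / (2 * sigma * sigma))
    s2 = 2 * sigma * sigma
    return (sigma * sigma / (2 * r * max(d, 1e-9))) * (
        math.exp(-((d - r) ** 2) / s2) - math.exp(-((d + r) ** 2) / s2)
    ) if d > 1e-9 else math.exp(-(r * r) / s2)


def expected_shell_occupancy(config: Optional[ClassifierConfig] = None) -> np.ndarray:
    """(20, n_shells) template matrix mu.

    mu[a, k] is the Gaussian-smeared contribution of type a's ideal
    side-chain heavy atoms to the mean density of shell k. Row order
    follows the fixed one-letter alphabet; glycine's row is all zero.
    """
    config = config or ClassifierConfig()
    edges = config.shell_edges
    radii = [0.5 * (edges[k] + edges[k + 1]) for k in range(config.n_shells)]
    max_d = edges[-1] - 0.05
    mu = np.zeros((N_TYPES, config.n_shells))
    for a, distances in SIDE_CHAIN_DISTANCES.items():
        row = AA_INDEX[a]
        for d in distances:
            d = min(d, max_d)
            for k, r in enumerate(radii):
                mu[row, k] += _gaussian_shell_average(d, r, config.atom_sigma)
    return mu


def classify_residue(features: np.ndarray, config: Optional[ClassifierConfig] = None,
                     templates: Optional[np.ndarray] = None) -> np.ndarray:
    """20-class probability row from shell features.

    For each type the template is scaled by a least-squares factor s
    clamped to [0.05, 20]; score(a) = -sum_k (f_k - s*mu[a,k])^2 (for
    glycine, whose template is empty, the residual is the features'
    total squared mass) and probabilities are softmax(score /
    temperature), floored and renormalized. The positive lower clamp on
    s makes an all-zero feature vector rank glycine strictly first.
    """
    config = config or ClassifierConfig()
    f = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite features")
    mu = templates if templates is not None else expected_shell_occupancy(config)
    var = (mu * mu).sum(axis=1)
    s = np.where(var > 0, mu @ f / np.where(var > 0, var, 1.0), 0.0)
    s = np.clip(s, 0.05, 20.0)
    resid = ((f[None, :] - s[:, None] * mu) ** 2).sum(axis=1)
    resid[var == 0] = (f * f).sum()  # glycine: empty template
    scores = -resid / config.softmax_temperature
    scores -= scores.max()
    p = np.exp(scores)
    p /= p.sum()
    p = np.maximum(p, config.probability_floor)
    return p / p.sum()


class BaselineClassifier:
    """Density-shell baseline classifier with per-model caching.

    Instances are callables matching the pluggable classifier contract:
    ``clf(model, dmap, chain, residue) -> probability row``.
    """

    def __init__(self, config: Optional[ClassifierConfig] = None):
        self.config = config or ClassifierConfig()
        self.templates = expected_shell_occupancy(self.config)
        self._tree_cache = {}

    def _trees(self, model: StructureModel, chain_id: str):
        key = (id(model), chain_id)
        if key not in self._tree_cache:
            self._tree_cache[key] = _foreign_trees(model, chain_id)
        return self._tree_cache[key]

    def __call__(self, model: StructureModel, dmap: DensityMap, chain: Chain,
                 residue: Residue) -> np.ndarray:
        other_tree, own_coords, owner, is_backbone = self._trees(model, chain.id)
        try:
            res_index = chain.residues.index(residue)
        except ValueError:
            res_index = -1
        # own side-chain atoms (CB included) are signal, everything else is not
        foreign = (owner != res_index) | is_backbone
        anchor = _anchor(residue)
        reach = self.config.shell_edges[-1] + 4.0 * self.config.atom_sigma + 2.0
        near = np.linalg.norm(own_coords - anchor, axis=1) <= reach
        coords = own_coords[foreign & near]
        foreign_tree = cKDTree(coords) if len(coords) else None
        features = shell_features(model, dmap, residue, self.config,
                                  neighbor_tree=other_tree,
                                  foreign_tree=foreign_tree,
                                  foreign_coords=coords)
        return classify_residue(features, self.config, self.templates)


def extract_profile(model: StructureModel, dmap: DensityMap, chain: Chain,
                    classifier: Optional[Callable] = None,
                    config: Optional[ClassifierConfig] = None) -> ResidueProfile:
    """One probability row per residue of the chain.

    Residues the classifier cannot handle get a uniform row and are
    flagged. Any callable with the baseline's signature may replace it.
    """
    if chain not in model.chains:
        model.get_chain(chain.id)  # raises KeyError if absent
    if classifier is None:
        classifier = BaselineClassifier(config)
    rows = np.empty((len(chain), N_TYPES))
    flagged = set()
    for i, residue in enumerate(chain.residues):
        try:
            rows[i] = classifier(model, dmap, chain, residue)
        except (FeatureError, ValueError):
            rows[i] = 1.0 / N_TYPES
            flagged.add(i)
    return ResidueProfile(chain_id=chain.id,
                          residue_keys=[r.key for r in chain.residues],
                          probs=rows, flagged=frozenset(flagged))


# ---------------------------------------------------------------------------
# profile tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["chain", "resnum", "icode"] + list(AA1)


def write_profile_table(profiles, path: str) -> None:
    """Write profiles as a tab-separated table (one row per residue)."""
    if isinstance(profiles, ResidueProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        for (num, icode), p in zip(prof.residue_keys, prof.probs):
            rows.append([prof.chain_id, num, icode or "."] + list(p))
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6e"
    )


def read_profile_table(path: str) -> dict:
    """Read a profile table; returns {chain_id: ResidueProfile}."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"icode": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing profile columns {missing}")
    out = {}
    for chain_id, sub in df.groupby("chain", sort=False):
        keys = [
            (int(n), "" if ic in (".", "") else str(ic))
            for n, ic in zip(sub["resnum"], sub["icode"])
        ]
        probs = sub[list(AA1)].to_numpy(dtype=float)
        probs = probs / probs.sum(axis=1, keepdims=True)  # absorb rounding
        out[str(chain_id)] = ResidueProfile(chain_id=str(chain_id),
                                            residue_keys=keys, probs=probs)
    return out
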