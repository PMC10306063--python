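"""Sliding-window register scanning and issue categorization.

Each protein chain is first identified against the target sequences from
its full density profile. Windows are then slid along every continuous
residue-number run, re-aligned against the targets, and compared with
the register implied by the model. A window whose best alignment has a
p-value below the threshold *and* disagrees with the model's register is
a candidate register error; runs of such windows with a common offset
are merged into categorized issue regions:

- ``register_shift``: the detected register differs from the model's and
  the model's residue identities do not match the target at the detected
  offset (the trace is offset relative to what was built);
- ``indexing_issue``: identities do match at the detected offset, so the
  identities are right but the residue numbering is inconsistent (e.g.
  an unmodelled loop ignored in the numbering);
- ``sequence_mismatch``: isolated model-vs-target letter disagreements
  (or UNK residues) inside otherwise consistent stretches;
- ``unassigned_chain``: no target sequence could be assigned to a chain
  of at least ``min_chain_length`` residues.

The model's register (``model_offset``) is anchored once per continuous
run by a mismatch-tolerant ('X'-wildcard Hamming) placement of the run's
claimed one-letter sequence in the assigned target and extrapolated
through the run by residue numbering, so that both indexing issues and
isolated mismatches remain detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alphabet import N_TYPES, seq_to_indices
from .profile_align import (AlignmentParams, WindowAlignment, alignment_pvalue,
                            best_gapless_alignment, certified_pvalue_bound,
                            count_offsets, logodds_matrix,
                            null_score_distribution, window_scores_matrix)
from .residue_classifier import ResidueProfile
from .structure_io import Chain, TargetSequence

CATEGORIES = ("register_shift", "indexing_issue", "sequence_mismatch", "unassigned_chain")


class UnassignedChainError(ValueError):
    """Scanning requested for a chain without a sequence assignment."""


@dataclass
class ScanConfig:
    window_length: int = 20
    step: int = 1
    pvalue_threshold: float = 0.14
    min_chain_length: int = 10
    merge_gap: int = 5

    def __post_init__(self):
        if self.window_length < 5:
            raise ValueError("window_length must be >= 5")
        if self.step < 1 or self.min_chain_length < 1:
            raise ValueError("step and min_chain_length must be >= 1")


@dataclass
class WindowCall:
    chain_id: str
    start: int  # author residue number of the first window residue
    end: int
    length: int
    best: WindowAlignment
    model_offset: Optional[int]
    status: str  # consistent | shifted | inconclusive

    @property
    def offset_delta(self) -> Optional[int]:
        if self.model_offset is None:
            return None
        return self.best.offset - self.model_offset


@dataclass
class IssueRegion:
    chain_id: str
    category: str
    start: int
    end: int
    offset: Optional[int] = None
    best_pvalue: Optional[float] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.category in ("register_shift", "indexing_issue") and not self.offset:
            raise ValueError(f"{self.category} region requires a non-zero offset")


@dataclass
class ChainAssignment:
    chain_id: str
    seq_id: Optional[str]
    pvalue: Optional[float]
    assigned: bool
    reason: Optional[str] = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _profile_runs(profile: ResidueProfile) -> list:
    """Continuous residue-number runs, as (start_index, end_index) pairs."""
    runs = []
    start = None
    keys = profile.residue_keys
    for i, (num, icode) in enumerate(keys):
        if icode != "":
            if start is not None:
                runs.append((start, i - 1))
                start = None
            continue
        if start is None:
            start = i
        elif num != keys[i - 1][0] + 1 or keys[i - 1][1] != "":
            runs.append((start, i - 1))
            start = i
    if start is not None:
        runs.append((start, len(keys) - 1))
    return runs


def anchor_offset(claimed: str, target: TargetSequence,
                  max_mismatch_fraction: float = 0.5) -> Optional[int]:
    """Target offset (0-based) that best matches a claimed sequence.

    'X' positions are wildcards; the placement minimizing the Hamming
    mismatch count wins, ties to the lowest offset. Returns None when no
    placement fits or the best one exceeds the mismatch budget.
    """
    L = len(claimed)
    if L == 0 or L > len(target):
        return None
    cl = seq_to_indices(claimed)
    tg = seq_to_indices(target.residues)
    sw = np.lib.stride_tricks.sliding_window_view(tg, L)
    informative = cl != N_TYPES
    mism = ((sw != cl) & informative).sum(axis=1)
    best = int(np.argmin(mism))
    n_informative = max(int(informative.sum()), 1)
    if mism[best] > max_mismatch_fraction * n_informative:
        return None
    return best


def assign_chain(profile: ResidueProfile, sequences: Sequence[TargetSequence],
                 config: Optional[ScanConfig] = None,
                 params: Optional[AlignmentParams] = None,
                 cache: Optional[dict] = None) -> ChainAssignment:
    """Identify the target sequence a chain's density profile comes from.

    The longest continuous run of the chain is aligned gaplessly against
    every target; the chain is assigned iff the best alignment's p-value
    clears the threshold. Chains shorter than ``min_chain_length`` are
    skipped (not failed).
    """
    config = config or ScanConfig()
    params = params or AlignmentParams(pvalue_threshold=config.pvalue_threshold)
    if len(profile) < config.min_chain_length:
        return ChainAssignment(profile.chain_id, None, None, False,
                               reason="below minimum length")
    runs = _profile_runs(profile)
    if not runs:
        return ChainAssignment(profile.chain_id, None, None, False,
                               reason="no continuous segment")
    s, e = max(runs, key=lambda r: r[1] - r[0])
    window = profile.probs[s : e + 1]
    if count_offsets(sequences, len(window)) == 0:
        return ChainAssignment(profile.chain_id, None, None, False,
                               reason="no sequence long enough")
    best = best_gapless_alignment(window, sequences, params)
    bound = certified_pvalue_bound(best.score, len(window), best.n_offsets,
                                   params.grid_step)
    if bound < config.pvalue_threshold:
        pvalue = bound  # certified upper bound; exact value not needed
    else:
        null = null_score_distribution(window, params, cache=cache)
        pvalue = alignment_pvalue(best.score, null, best.n_offsets)
    assigned = pvalue < config.pvalue_threshold
    return ChainAssignment(profile.chain_id, best.seq_id if assigned else None,
                           pvalue, assigned,
                           reason=None if assigned else "no significant alignment")


def scan_chain(profile: ResidueProfile, chain: Chain, assignment: ChainAssignment,
               sequences: Sequence[TargetSequence],
               config: Optional[ScanConfig] = None,
               params: Optional[AlignmentParams] = None,
               cache: Optional[dict] = None) -> list:
    """Window calls along every continuous run of an assigned chain."""
    config = config or ScanConfig()
    params = params or AlignmentParams(pvalue_threshold=config.pvalue_threshold)
    if not assignment.assigned:
        raise UnassignedChainError(
            f"chain {profile.chain_id}: report unassigned_chain instead of scanning"
        )
    if cache is None:
        cache = {}
    target = next(s for s in sequences if s.id == assignment.seq_id)
    claimed = "".join(r.type1 for r in chain.residues)
    runs = _profile_runs(profile)
    # fallback anchor from the longest anchorable run, extrapolated by numbering
    fallback = None
    for s, e in sorted(runs, key=lambda r: r[0] - r[1]):
        a = anchor_offset(claimed[s : e + 1], target)
        if a is not None:
            fallback = (a, chain.residues[s].number)
            break
    seq_indices = [(seq, seq_to_indices(seq.residues)) for seq in sequences]
    calls = []
    L = config.window_length
    for s, e in runs:
        n = e - s + 1
        if n >= L:
            starts = list(range(s, e - L + 2, config.step))
            wlen = L
        elif n >= config.min_chain_length:
            starts = [s]
            wlen = n
        else:
            continue
        run_anchor = anchor_offset(claimed[s : e + 1], target)
        n_offsets = count_offsets(sequences, wlen)
        if n_offsets == 0:
            continue
        # score every window of the run against every offset at once
        lo_run = logodds_matrix(profile.probs[s : e + 1], params)
        best_by_window = {}
        for seq, idx in seq_indices:
            C = window_scores_matrix(lo_run, idx, wlen)
            if C.shape[1] == 0:
                continue
            offs = np.argmax(C, axis=1)
            tops = C[np.arange(len(C)), offs]
            for w in starts:
                row = w - s
                score = float(tops[row])
                cur = best_by_window.get(w)
                if cur is None or score > cur.score:
                    best_by_window[w] = WindowAlignment(
                        seq_id=seq.id, offset=int(offs[row]), score=score,
                        n_offsets=n_offsets)
        for w in starts:
            if run_anchor is not None:
                model_offset = run_anchor + (w - s)
            elif fallback is not None:
                model_offset = fallback[0] + (chain.residues[w].number - fallback[1])
                if not 0 <= model_offset <= len(target) - wlen:
                    model_offset = None
            else:
                model_offset = None
            best = best_by_window[w]
            bound = certified_pvalue_bound(best.score, wlen, best.n_offsets,
                                           params.grid_step)
            if bound < config.pvalue_threshold:
                best.pvalue = bound  # certified upper bound suffices
            else:
                null = null_score_distribution(profile.probs[w : w + wlen],
                                               params, cache=cache)
                best.pvalue = alignment_pvalue(best.score, null, best.n_offsets)
            if best.pvalue >= config.pvalue_threshold:
                status = "inconclusive"
            elif (model_offset is not None and best.offset == model_offset
                  and best.seq_id == assignment.seq_id):
                status = "consistent"
            else:
                status = "shifted"
            calls.append(WindowCall(
                chain_id=profile.chain_id,
                start=chain.residues[w].number,
                end=chain.residues[w + wlen - 1].number,
                length=wlen, best=best, model_offset=model_offset, status=status,
            ))
    return calls


def region_bounds(merged_windows: Sequence[WindowCall]) -> tuple:
    """Region bounds from a merged run of shifted windows (midpoint rule).

    The first half-window and last half-window are trimmed so the region
    approximates the actually shifted residue span; a single shifted
    window collapses to its midpoint.
    """
    first = merged_windows[0]
    last = merged_windows[-1]
    start = first.start + first.length // 2
    end = last.end - last.length // 2
    if end < start:
        start = end = (first.start + last.end + 1) // 2
    return start, end


def categorize(calls: Sequence[WindowCall], chain: Chain, target: TargetSequence,
               config: Optional[ScanConfig] = None) -> list:
    """Merge window calls into categorized issue regions."""
    config = config or ScanConfig()
    regions = []
    # --- merge shifted windows with a common offset delta ---
    groups = []
    for call in calls:
        if call.status != "shifted":
            continue
        delta = call.offset_delta
        if groups:
            prev_group = groups[-1]
            prev = prev_group[-1]
            if (call.offset_delta == prev.offset_delta
                    and call.best.seq_id == prev.best.seq_id
                    and call.start - prev.start <= config.merge_gap):
                prev_group.append(call)
                continue
        groups.append([call])
    claimed_by_num = {r.number: r.type1 for r in chain.residues if r.icode == ""}
    shifted_residues = set()
    for group in groups:
        start, end = region_bounds(group)
        delta = group[0].offset_delta
        best_p = min(c.best.pvalue for c in group)
        if delta is None:
            # no register anchor at all: the shift magnitude is unknowable,
            # so no register_shift region can be stated for this group
            continue
        # identities right at the detected offset => numbering problem
        letters = [claimed_by_num.get(n) for n in range(start, end + 1)]
        tg = target.residues
        base = group[0].best.offset + (start - group[0].start)
        matches = 0
        informative = 0
        for i, a in enumerate(letters):
            pos = base + i
            if a is None or a == "X" or not 0 <= pos < len(tg):
                continue
            informative += 1
            matches += a == tg[pos]
        category = "indexing_issue" if informative and matches == informative else "register_shift"
        regions.append(IssueRegion(group[0].chain_id, category, start, end,
                                   offset=int(delta), best_pvalue=best_p))
        shifted_residues.update(range(start, end + 1))
    # --- isolated mismatches inside consistent stretches ---
    mismatch_nums = []
    covered = {}
    for call in calls:
        if call.status != "consistent" or call.model_offset is None:
            continue
        for i in range(call.length):
            covered.setdefault(call.start + i, call.model_offset + i)
    for num, pos in sorted(covered.items()):
        if num in shifted_residues:
            continue
        a = claimed_by_num.get(num)
        if a is None or not 0 <= pos < len(target):
            continue
        if a == "X" or a != target.residues[pos]:
            mismatch_nums.append(num)
    chain_id = calls[0].chain_id if calls else chain.id
    for num in mismatch_nums:
        if regions and regions[-1].category == "sequence_mismatch" and regions[-1].end == num - 1:
            regions[-1].end = num
        else:
            regions.append(IssueRegion(chain_id, "sequence_mismatch", num, num))
    regions.sort(key=lambda r: (r.start, r.end))
    return regions


def unassigned_region(chain: Chain, assignment: ChainAssignment) -> IssueRegion:
    """Whole-chain issue region for a chain that could not be assigned."""
    return IssueRegion(chain.id, "unassigned_chain",
                       chain.residues[0].number, chain.residues[-1].number,
                       best_pvalue=assignment.pvalue)
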