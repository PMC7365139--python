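"""Orthogonal sgRNA:promoter library design.

Each library member starts from a random 15-nt *pre-sequence*: the
3'-most 14 nucleotides of a CRISPRi operator (which include the
specificity-conveying seed) plus one nucleotide that becomes the first,
degenerate position of the adjacent NGG PAM.  Appending ``GG`` completes
the PAM, and placing the 17-nt operator:PAM block between the -35 and -10
hexamers of a constitutive scaffold yields a repressible promoter; the
cognate sgRNA operator is the promoter's -35 hexamer plus the first 14 nt
of the pre-sequence (20 nt total).

Candidate pairs are filtered for spurious PAM creation and BsaI sites,
screened against a genome for off-target binding (suffix-match and
seed-mismatch rules), thinned to a mutually dissimilar core via a
match-weight graph heuristic, expanded into diverse candidate sets, and
scored with 3'-weighted position penalties.  Finally, promoters are
standardized to 105 bp with randomly generated, motif-screened
insulators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PreSequence",
    "Scaffold",
    "SCAFFOLDS",
    "GuideDesign",
    "GenomeTarget",
    "MatchGraph",
    "generate_presequences",
    "build_pair",
    "offtarget_screen",
    "match_weight",
    "select_core_subset",
    "expand_diverse_sets",
    "score_and_pick",
    "generate_insulator",
    "insulate_promoter",
    "DEFAULT_FORBIDDEN_MOTIFS",
    "design_library",
]

_ALPHABET = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
BSAI = ("GGTCTC", "GAGACC")  # recognition site and its reverse complement


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PreSequence:
    """14 operator nt + 1 degenerate PAM nt (15 nt total)."""

    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != 15:
            raise ValueError("pre-sequence must be 15 nt")
        if set(self.seq) - set(_ALPHABET):
            raise ValueError("pre-sequence alphabet is ACGT")

    @property
    def operator14(self) -> str:
        return self.seq[:14]

    @property
    def pam_first(self) -> str:
        return self.seq[14]


@dataclass(frozen=True)
class Scaffold:
    """Constitutive promoter scaffold donating -35/-10 hexamers and context.

    The lambda PR hexamers are the canonical ones; the apFAB126 hexamers
    and both flank sequences are synthetic representative context (the
    source promoters' full sequences are not redistributed here) and are
    plain configuration: supply your own Scaffold for exact designs.
    """

    name: str
    minus35: str
    minus10: str
    upstream: str
    downstream: str

    def __post_init__(self) -> None:
        if len(self.minus35) != 6 or len(self.minus10) != 6:
            raise ValueError("-35 and -10 elements must be hexamers")


SCAFFOLDS = {
    "apFAB126": Scaffold(
        name="apFAB126",
        minus35="TTGACA",
        minus10="TATAAT",
        upstream="TTATCAAAAAGAGT",
        downstream="ATACTAGAGAAAGA",
    ),
    "PR": Scaffold(
        name="PR",
        minus35="TTGACT",
        minus10="GATAAT",
        upstream="TAACACCGTGCGTG",
        downstream="GGTTGCATGTACTA",
    ),
}


@dataclass(frozen=True)
class GuideDesign:
    pre: PreSequence
    scaffold: str
    promoter_core: str
    sgrna_operator: str
    handle: str
    verdicts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sgrna_operator) != 20:
            raise ValueError("sgRNA operator must be 20 nt")

    @property
    def operator_pam(self) -> str:
        """20-nt operator followed by the completed NGG PAM (23 nt)."""
        return self.sgrna_operator + self.pre.pam_first + "GG"


# 82-nt S. pyogenes handle + terminator placeholder; constant across designs,
# synthetic stand-in for the published constant region.
DEFAULT_HANDLE = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTG"
    "GCACCGAGTCGGTGCTTTTTT"
)
assert len(DEFAULT_HANDLE) == 82


@dataclass(frozen=True)
class GenomeTarget:
    """Genome sequence plus essential-feature intervals (0-based, half-open)."""

    genome: str
    essential_features: tuple[tuple[int, int, str], ...] = ()  # (start, end, strand)

    def __post_init__(self) -> None:
        L = len(self.genome)
        for start, end, strand in self.essential_features:
            if not (0 <= start < end <= L):
                raise ValueError(f"feature ({start}, {end}) outside genome bounds")
            if strand not in ("+", "-", "."):
                raise ValueError(f"bad strand {strand!r}")


class RejectedDesign(ValueError):
    """A pre-sequence whose promoter fails the construction filters."""


def generate_presequences(n: int, seed: int | np.random.Generator = 0) -> list[PreSequence]:
    """Draw ``n`` random pre-sequences with ~40% GC content.

    Each position is G or C with probability 0.4 (0.2 each) and A or T
    with probability 0.6 (0.3 each); deterministic under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [0.3, 0.2, 0.2, 0.3]  # A, C, G, T
    draws = rng.choice(4, size=(n, 15), p=probs)
    lut = np.array(list(_ALPHABET))
    return [PreSequence("".join(lut[row])) for row in draws]


def _pam_positions(seq: str, second: str) -> list[tuple[int, int]]:
    """(start, end) windows of NGG (second='G') or NAG (second='A') PAMs.

    Sense strand only: these are the PAMs in the orientation an sgRNA uses
    to target this promoter, the relevant class for spurious-repression
    filtering.
    """
    return [
        (i, i + 3)
        for i in range(len(seq) - 2)
        if seq[i + 1] == second and seq[i + 2] == "G"
    ]


def build_pair(
    pre: PreSequence, scaffold: str = "apFAB126", handle: str = DEFAULT_HANDLE
) -> GuideDesign:
    """Construct the promoter and sgRNA for one pre-sequence.

    The promoter core is ``upstream + (-35) + pre + GG + (-10) + downstream``
    (the 17-nt operator:PAM block exactly fills the -35/-10 spacer), and
    the sgRNA operator is the -35 hexamer plus the first 14 pre-sequence
    nucleotides.  Raises :class:`RejectedDesign` if insertion creates more
    than one additional sense-strand NGG PAM or any additional NAG PAM
    relative to the bare scaffold (the designed PAM is the one permitted
    addition; a PAM counts as additional when its window overlaps the
    inserted operator:PAM block), or if the promoter contains a BsaI
    recognition site on either strand.
    """
    if scaffold not in SCAFFOLDS:
        raise ValueError(f"unknown scaffold {scaffold!r}")
    sc = SCAFFOLDS[scaffold]
    insert = pre.seq + "GG"
    promoter = sc.upstream + sc.minus35 + insert + sc.minus10 + sc.downstream
    ins_start = len(sc.upstream) + 6
    ins_end = ins_start + len(insert)

    def overlaps_insert(window: tuple[int, int]) -> bool:
        return window[0] < ins_end and window[1] > ins_start

    # BsaI first: an unclonable part is rejected regardless of PAM content
    for site in BSAI:
        if site in promoter:
            raise RejectedDesign("promoter contains a BsaI recognition site")
    extra_ngg = sum(1 for w in _pam_positions(promoter, "G") if overlaps_insert(w))
    extra_nag = sum(1 for w in _pam_positions(promoter, "A") if overlaps_insert(w))
    if extra_ngg > 1:
        raise RejectedDesign(
            f"insertion creates {extra_ngg - 1} NGG PAM(s) beyond the designed one"
        )
    if extra_nag > 0:
        raise RejectedDesign(f"insertion creates {extra_nag} secondary (NAG) PAM(s)")
    return GuideDesign(
        pre=pre,
        scaffold=scaffold,
        promoter_core=promoter,
        sgrna_operator=sc.minus35 + pre.operator14,
        handle=handle,
    )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def offtarget_screen(d: GuideDesign, g: GenomeTarget) -> str:
    """Screen one design against a genome; returns the first failing rule.

    Rules, in reporting order, scanning both strands:

    1. ``fail_10nt_essential`` -- the 3'-most 10 nt of the operator:PAM
       occur at a site overlapping an essential feature;
    2. ``fail_12nt_anywhere`` -- the 3'-most 12 nt occur anywhere;
    3. ``fail_seed_mismatch`` -- a genomic site matches the 13-nt seed
       (3'-most 13 operator nt) exactly or with one mismatch and is
       immediately followed by an NGG or NAG PAM;
    4. ``pass`` otherwise.
    """
    if not g.genome:
        raise ValueError("genome must be non-empty")
    genome = g.genome.upper()
    L = len(genome)
    strands = ((genome, False), (revcomp(genome), True))
    op_pam = d.operator_pam

    def genome_window(pos: int, length: int, rc: bool) -> tuple[int, int]:
        # map a match on the scanned strand back to forward-genome coords
        if not rc:
            return pos, pos + length
        return L - pos - length, L - pos

    def hits_essential(start: int, end: int) -> bool:
        return any(start < fe and fs < end for fs, fe, _ in g.essential_features)

    suf10, suf12 = op_pam[-10:], op_pam[-12:]
    for strand_seq, rc in strands:
        for pos in _find_all(strand_seq, suf10):
            if hits_essential(*genome_window(pos, 10, rc)):
                return "fail_10nt_essential"
    for strand_seq, rc in strands:
        if suf12 in strand_seq:
            return "fail_12nt_anywhere"
    seed = d.sgrna_operator[-13:]
    seed_arr = _encode(seed)
    for strand_seq, rc in strands:
        arr = _encode(strand_seq)
        n_win = L - 13 - 2  # need 3 nt of PAM after the seed
        if n_win <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, 13)[:n_win]
        mism = (windows != seed_arr).sum(axis=1)
        for pos in np.nonzero(mism <= 1)[0]:
            pam = strand_seq[pos + 13 : pos + 16]
            if pam[1:] in ("GG", "AG"):
                return "fail_seed_mismatch"
    return "pass"


def match_weight(a: PreSequence | str, b: PreSequence | str) -> int:
    """Number of co-occurring nucleotides between two pre-sequences (0-15)."""
    sa = a.seq if isinstance(a, PreSequence) else a
    sb = b.seq if isinstance(b, PreSequence) else b
    if len(sa) != len(sb):
        raise ValueError("pre-sequences must have equal length")
    return sum(1 for x, y in zip(sa, sb) if x == y)


class MatchGraph:
    """Complete graph over pre-sequences; edges weighted by nucleotide matches."""

    def __init__(self, pres: Sequence[PreSequence]):
        self.pres = list(pres)
        self._mat = np.stack([_encode(p.seq) for p in self.pres])

    def __len__(self) -> int:
        return len(self.pres)

    @property
    def n_edges(self) -> int:
        n = len(self.pres)
        return n * (n - 1) // 2

    def weight(self, i: int, j: int) -> int:
        return int((self._mat[i] == self._mat[j]).sum())

    def weight_matrix(self) -> np.ndarray:
        """Full symmetric weight matrix (zero diagonal), int16."""
        n = len(self.pres)
        w = np.zeros((n, n), dtype=np.int16)
        for pos in range(self._mat.shape[1]):
            col = self._mat[:, pos]
            w += (col[:, None] == col[None, :]).astype(np.int16)
        np.fill_diagonal(w, 0)
        return w

    def max_weight(self) -> int:
        w = self.weight_matrix()
        return int(w.max()) if len(self.pres) > 1 else 0


def _subset_total(w: np.ndarray, idx: Sequence[int]) -> int:
    sub = w[np.ix_(idx, idx)]
    return int(sub.sum() // 2)


def select_core_subset(
    pres: Sequence[PreSequence],
    core_size: int = 100,
    refinement_loops: int = 4,
    seed: int = 0,
) -> tuple[list[int], int]:
    """Greedy + swap heuristic for a low-total-match-weight core subset.

    Phase 1 sorts all edges by ascending weight (ties by vertex index) and
    collects vertices from the lightest edges until ``core_size`` are
    gathered.  Phase 2 loops ``refinement_loops`` times over the excluded
    pre-sequences; each is tentatively added and the member contributing
    the largest summed weight to the enlarged subset is discarded, so the
    total pairwise weight never increases.  The procedure is deterministic;
    ``seed`` is accepted for interface uniformity but unused.

    Returns (member indices, total pairwise weight).
    """
    n = len(pres)
    if n < core_size:
        raise ValueError(f"need at least core_size={core_size} pre-sequences, got {n}")
    g = MatchGraph(pres)
    w = g.weight_matrix().astype(np.int64)
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, w[iu, ju]))  # weight, then (i, j) index order
    members: list[int] = []
    chosen = np.zeros(n, dtype=bool)
    for e in order:
        for v in (int(iu[e]), int(ju[e])):
            if not chosen[v]:
                chosen[v] = True
                members.append(v)
                if len(members) == core_size:
                    break
        if len(members) == core_size:
            break
    member_set = set(members)
    for _ in range(refinement_loops):
        for cand in range(n):
            if cand in member_set:
                continue
            trial = sorted(member_set) + [cand]
            sub = w[np.ix_(trial, trial)]
            contrib = sub.sum(axis=1)
            worst = trial[int(np.argmax(contrib))]  # ties -> first (lowest position)
            if worst != cand:
                member_set.remove(worst)
                member_set.add(cand)
    final = sorted(member_set)
    return final, _subset_total(w, final)


def expand_diverse_sets(
    pres: Sequence[PreSequence],
    max_pair_weight: int = 5,
    min_size: int = 10,
    seed: int = 0,
    budget: int = 10000,
) -> list[tuple[int, ...]]:
    """Randomized growth of mutually dissimilar pre-sequence sets.

    Seeds are all pairs whose match weight is at most ``max_pair_weight``;
    each expansion attempt grows a random seed by repeatedly adding a
    random compatible pre-sequence (one keeping every pairwise weight
    within the cap) until none remains.  All distinct maximal sets of size
    at least ``min_size`` found within ``budget`` attempts are returned,
    sorted canonically.  An empty result is legitimate when no pair
    qualifies.
    """
    rng = np.random.default_rng(seed)
    g = MatchGraph(pres)
    n = len(pres)
    w = g.weight_matrix()
    compat = w <= max_pair_weight
    np.fill_diagonal(compat, False)
    iu, ju = np.triu_indices(n, k=1)
    seed_pairs = [(int(a), int(b)) for a, b in zip(iu, ju) if compat[a, b]]
    if not seed_pairs:
        return []
    found: set[tuple[int, ...]] = set()
    for _ in range(budget):
        a, b = seed_pairs[int(rng.integers(len(seed_pairs)))]
        members = [a, b]
        ok = compat[a] & compat[b]
        while True:
            cand = np.nonzero(ok)[0]
            if len(cand) == 0:
                break
            pick = int(cand[int(rng.integers(len(cand)))])
            members.append(pick)
            ok &= compat[pick]
            ok[pick] = False
        if len(members) >= min_size:
            found.add(tuple(sorted(members)))
    return sorted(found)


def score_and_pick(
    sets: Sequence[Sequence[int]],
    pres: Sequence[PreSequence],
    position_weights: Sequence[float] = tuple(range(1, 16)),
) -> tuple[int, ...]:
    """Choose the candidate set with the lowest mean 3'-weighted edge score.

    An edge's score sums ``position_weights[i]`` over matching positions
    ``i``; weights ascend toward the 3' end, so 3' matches (which fall in
    the sgRNA seed) are punished hardest.  Ties break lexicographically on
    the sorted membership.
    """
    if not sets:
        raise ValueError("no candidate sets to score")
    pw = list(position_weights)
    if len(pw) != 15 or any(v <= 0 for v in pw):
        raise ValueError("need 15 positive position weights")
    if any(b < a for a, b in zip(pw, pw[1:])):
        raise ValueError("position weights must be non-decreasing toward the 3' end")

    def edge_score(i: int, j: int) -> float:
        return sum(
            pw[k] for k, (x, y) in enumerate(zip(pres[i].seq, pres[j].seq)) if x == y
        )

    def set_score(s: Sequence[int]) -> float:
        pairs = list(itertools.combinations(sorted(s), 2))
        if not pairs:
            return 0.0
        return sum(edge_score(i, j) for i, j in pairs) / len(pairs)

    ranked = sorted((set_score(s), tuple(sorted(s))) for s in sets)
    return ranked[0][1]


#: Motifs excluded from insulators: sigma-70 promoter hexamers, strong
#: Shine-Dalgarno cores, BsaI and common cloning-enzyme sites, mononucleotide
#: repeats, and the TetR O2 operator.  A deliberately compact default; the
#: full regulatory-motif catalogs of the insulation literature are supplied
#: by the caller.
DEFAULT_FORBIDDEN_MOTIFS = (
    "TTGACA",
    "TATAAT",
    "AGGAGG",
    "GGAGG",
    "GGTCTC",
    "GAATTC",
    "GGATCC",
    "AAGCTT",
    "TCTAGA",
    "ACTAGT",
    "GCGGCCGC",
    "AAAAAAAA",
    "TTTTTTTT",
    "GGGGGGGG",
    "CCCCCCCC",
    "TCCCTATCAGTGATAGAGA",
)


def generate_insulator(
    length: int = 70,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10000,
) -> str:
    """Rejection-sample a random sequence free of forbidden motifs.

    Both strands are scanned.  Deterministic under the seed.  Raises
    RuntimeError if no acceptable sequence is found within
    ``max_attempts`` (e.g. an unsatisfiable motif catalog).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lut = np.array(list(_ALPHABET))
    for _ in range(max_attempts):
        seq = "".join(lut[rng.integers(0, 4, size=length)])
        rc = revcomp(seq)
        if any(m in seq or m in rc for m in forbidden_motifs):
            continue
        return seq
    raise RuntimeError(
        f"no motif-free insulator found in {max_attempts} attempts; "
        "motif catalog may be unsatisfiable"
    )


def insulate_promoter(core: str, insulator: str, total_length: int = 105) -> str:
    """Prepend an insulator, truncated from its 5' end, to a fixed total length."""
    if len(core) > total_length:
        raise ValueError(f"core promoter longer than {total_length} bp")
    needed = total_length - len(core)
    return insulator[len(insulator) - needed :] + core


def design_library(
    genome: GenomeTarget | None,
    n_candidates: int = 300,
    scaffold: str = "apFAB126",
    core_size: int = 30,
    min_set_size: int = 5,
    max_pair_weight: int = 5,
    seed: int = 0,
    expansion_budget: int = 2000,
) -> dict:
    """End-to-end pipeline: generate, filter, screen, diversify, insulate.

    Returns a report dict with the surviving designs, the chosen diverse
    set, and per-stage counts.  Defaults are desk-scale; the published
    pipeline ran the same stages at 3,000 candidates and core size 100.
    """
    rng = np.random.default_rng(seed)
    pres = generate_presequences(n_candidates, rng)
    built: list[GuideDesign] = []
    kept_pres: list[PreSequence] = []
    n_rejected_build = 0
    for p in pres:
        try:
            d = build_pair(p, scaffold)
        except RejectedDesign:
            n_rejected_build += 1
            continue
        built.append(d)
        kept_pres.append(p)
    if genome is not None:
        screened, spres = [], []
        for d, p in zip(built, kept_pres):
            verdict = offtarget_screen(d, genome)
            if verdict == "pass":
                screened.append(d)
                spres.append(p)
        built, kept_pres = screened, spres
    if len(kept_pres) < core_size:
        raise ValueError(
            f"only {len(kept_pres)} designs survive screening; "
            f"core_size={core_size} unreachable"
        )
    core_idx, core_weight = select_core_subset(kept_pres, core_size=core_size)
    core_pres = [kept_pres[i] for i in core_idx]
    sets = expand_diverse_sets(
        core_pres,
        max_pair_weight=max_pair_weight,
        min_size=min_set_size,
        seed=seed,
        budget=expansion_budget,
    )
    chosen = score_and_pick(sets, core_pres) if sets else ()
    insulator = generate_insulator(seed=rng)
    final = []
    for local_i in chosen:
        d = built[core_idx[local_i]]
        final.append(
            {
                "pre": d.pre.seq,
                "sgrna": d.sgrna_operator + d.handle,
                "promoter": insulate_promoter(d.promoter_core, insulator),
            }
        )
    return {
        "n_candidates": n_candidates,
        "n_rejected_build": n_rejected_build,
        "n_screened": len(built),
        "core_indices": core_idx,
        "core_total_weight": core_weight,
        "n_diverse_sets": len(sets),
        "chosen_set": chosen,
        "library": final,
    }
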