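"""Per-sample variant calling with dual algorithms and error reconciliation.

The genotyping strategy runs two complementary callers over the same
pileups — a read-ratio caller (sensitive to allele balance) and a diploid
genotype-likelihood caller (sensitive to low-level variants and able to call
both-non-reference genotypes) — and resolves their disagreements through a
five-class error taxonomy:

1. ``sequencing_error``  — likelihood-only calls without ratio or haplotype
   support are rejected;
2. ``chimera``           — a third dominant haplotype cluster that is a
   single-crossover recombinant of the two major clusters is removed and
   both callers rerun;
3. ``strand_bias_misalignment`` — variants (typically indels) supported on
   one strand only, with clean opposing-strand coverage, are recomputed from
   the clean strand;
4. ``tri_allelic``       — both-non-reference genotypes are accepted from
   the likelihood caller;
5. ``homopolymer``       — variants in homopolymer context (run length >= 4)
   are accepted when their allele fractions are consistent on both strands.

Reads are finally phased by clustering their bases at heterozygous sites,
yielding two full-length allele sequences per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io import SeqRead

log = logging.getLogger("mhcamplicon")

A, C, G, T, DEL, UNALIGNED = 0, 1, 2, 3, 4, 5
_CODE = np.full(256, UNALIGNED, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_BASES = "ACGT"
_GENOTYPES = [(i, j) for i in range(4) for j in range(i, 4)]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class CallerConfig:
    """Thresholds for alignment, calling, reconciliation and phasing."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    min_identity: float = 0.80
    min_minor_frac: float = 0.20       # support floor for any genotype base
    het_minor_frac: float = 0.35       # ratio caller: het only near 50:50
    max_minor_frac_hom: float = 0.05   # hom call when minor fraction <= this
    min_qual: float = 40.0             # Phred-scaled confidence cutoff
    homopolymer_min_len: int = 4
    cluster_frac: float = 0.05         # dominant haplotype cluster threshold
    strand_min_cov: int = 10
    phase_ambiguity_frac: float = 0.10
    default_qual: int = 30


@dataclass
class VariantCall:
    pos: int                         # 0-based
    ref: str
    genotype: tuple[str, str] | None  # None = no-call
    caller: str                       # "ratio" | "likelihood" | "both"
    qual: float | None = None
    status: str = "raw"               # concordant | reconciled:<cls> | rejected:<cls> | ...
    flags: set = field(default_factory=set)

    def is_variant(self) -> bool:
        return self.genotype is not None and any(b != self.ref for b in self.genotype)

    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]


@dataclass
class SitePileup:
    """Per-site pileup summary with strand bookkeeping."""

    pos: int
    counts_fwd: np.ndarray           # length-4 base counts on + strand
    counts_rev: np.ndarray
    del_fwd: int
    del_rev: int
    homopolymer: bool

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


@dataclass
class PhasedPair:
    haplotypes: tuple[str, str]
    support: tuple[int, int]
    chimera_clusters_removed: int = 0


class PhaseAmbiguousError(RuntimeError):
    """Competing phasings within the ambiguity band; no safe tie-break."""


@dataclass
class SampleCallSet:
    sample: str
    final_calls: list[VariantCall]
    ratio_calls: list[VariantCall]
    likelihood_calls: list[VariantCall]
    phased: PhasedPair | None
    n_reads_used: int
    n_reads_discarded: int
    reconciliation_notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Alignment and pileups
# ---------------------------------------------------------------------------

def homopolymer_mask(reference: str, min_len: int) -> np.ndarray:
    """True at columns inside or adjacent to a homopolymer run >= min_len."""
    L = len(reference)
    mask = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        j = i
        while j < L and reference[j] == reference[i]:
            j += 1
        if j - i >= min_len:
            mask[max(0, i - 1):min(L, j + 1)] = True
        i = j
    return mask


def _make_aligner(cfg: CallerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    # glocal: end gaps free so a full-length amplicon can overhang slightly
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class AlignedSample:
    """Per-read base calls projected onto reference columns, plus pileups.

    ``base_matrix[i, j]`` holds the code (0..3, DEL=4, UNALIGNED=5) of read i
    at reference column j. Insertions relative to the reference are tallied
    separately. Deletions are left-aligned within homopolymer runs before
    being recorded, which removes alignment-dialect ambiguity.
    """

    reference: str
    base_matrix: np.ndarray            # (n_reads, L) uint8
    strands: np.ndarray                # (n_reads,) 0='+', 1='-'
    read_ids: list[str]
    mean_qual: np.ndarray              # per-column mean Phred quality
    n_discarded: int
    homopolymer: np.ndarray            # per-column context flag

    def pileup_arrays(self, row_mask: np.ndarray | None = None):
        """(counts[2, L, 4], dels[2, L]) over the selected reads."""
        mat = self.base_matrix if row_mask is None else self.base_matrix[row_mask]
        strands = self.strands if row_mask is None else self.strands[row_mask]
        L = mat.shape[1]
        counts = np.zeros((2, L, 4), dtype=np.int64)
        dels = np.zeros((2, L), dtype=np.int64)
        for s in (0, 1):
            sub = mat[strands == s]
            if not sub.size:
                continue
            for b in range(4):
                counts[s, :, b] = (sub == b).sum(axis=0)
            dels[s] = (sub == DEL).sum(axis=0)
        return counts, dels

    def site(self, pos: int) -> SitePileup:
        counts, dels = self.pileup_arrays()
        return SitePileup(pos, counts[0, pos], counts[1, pos],
                          int(dels[0, pos]), int(dels[1, pos]),
                          bool(self.homopolymer[pos]))


def _project_alignment(aln, read_seq: str, L: int) -> np.ndarray:
    """Project one pairwise alignment onto reference columns."""
    row = np.full(L, UNALIGNED, dtype=np.uint8)
    tgt_blocks, qry_blocks = aln.aligned
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(tgt_blocks, qry_blocks):
        if prev_t_end is not None and t0 > prev_t_end and q0 == prev_q_end:
            row[prev_t_end:t0] = DEL  # deletion in the read
        row[t0:t1] = encode(read_seq[q0:q1])
        prev_t_end, prev_q_end = t1, q1
    return row


def _left_align_dels(row: np.ndarray, ref_codes: np.ndarray) -> np.ndarray:
    """Shift each deletion to the leftmost equivalent column of its run."""
    del_pos = np.nonzero(row == DEL)[0]
    for pos in del_pos:
        p = pos
        while p > 0 and ref_codes[p - 1] == ref_codes[pos] and row[p - 1] != DEL:
            p -= 1
        if p != pos:
            row[pos] = row[p]  # the base observed there slides right
            row[p] = DEL
    return row


def align_reads(reads: list[SeqRead], reference: str,
                cfg: CallerConfig | None = None) -> AlignedSample:
    """Align per-sample reads to the locus reference and build pileups.

    Reads whose length equals the reference take a fast vectorised path
    (column-identity mapping); length-discordant reads are aligned with an
    affine-gap glocal aligner. Reads under ``cfg.min_identity`` identity are
    discarded and counted.
    """
    cfg = cfg or CallerConfig()
    L = len(reference)
    ref_codes = encode(reference)
    rows, strands, ids, quals = [], [], [], []
    n_discarded = 0
    aligner = None
    for read in reads:
        if len(read.seq) == L:
            codes = encode(read.seq)
            identity = float((codes == ref_codes).mean())
            if identity < cfg.min_identity:
                n_discarded += 1
                continue
            row = codes
        else:
            if aligner is None:
                aligner = _make_aligner(cfg)
            aln = aligner.align(reference, read.seq)[0]
            row = _project_alignment(aln, read.seq, L)
            aligned = row != UNALIGNED
            matched = (row[aligned] == ref_codes[aligned]).sum()
            if not aligned.any() or matched / aligned.sum() < cfg.min_identity:
                n_discarded += 1
                continue
            row = _left_align_dels(row, ref_codes)
        rows.append(row)
        strands.append(0 if read.strand == "+" else 1)
        ids.append(read.id)
        q = read.qual
        if q is not None and len(q) == L:
            quals.append(np.asarray(q, dtype=np.float64))
        else:
            quals.append(np.full(L, float(cfg.default_qual)))
    if rows:
        base_matrix = np.vstack(rows)
        mean_qual = np.vstack(quals).mean(axis=0)
    else:
        base_matrix = np.zeros((0, L), dtype=np.uint8)
        mean_qual = np.full(L, float(cfg.default_qual))
    return AlignedSample(
        reference=reference,
        base_matrix=base_matrix,
        strands=np.asarray(strands, dtype=np.int8),
        read_ids=ids,
        mean_qual=mean_qual,
        n_discarded=n_discarded,
        homopolymer=homopolymer_mask(reference, cfg.homopolymer_min_len),
    )


# ---------------------------------------------------------------------------
# Callers
# ---------------------------------------------------------------------------

def _phred_to_err(q: np.ndarray) -> np.ndarray:
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def _site_loglik(counts4: np.ndarray, err: float) -> np.ndarray:
    """log10-likelihood of the 10 unordered diploid genotypes at one site."""
    p_match = 1.0 - err
    p_mis = err / 3.0
    logs = np.empty(len(_GENOTYPES))
    for k, (a, b) in enumerate(_GENOTYPES):
        probs = np.full(4, p_mis)
        probs[a] += (p_match - p_mis) / 2.0
        probs[b] += (p_match - p_mis) / 2.0
        logs[k] = float(counts4 @ np.log10(probs))
    return logs


def _likelihood_genotype(counts4: np.ndarray, err: float, ref_code: int):
    """(best genotype, Phred confidence vs next-best, confidence vs hom-ref)."""
    logs = _site_loglik(counts4, err)
    order = np.argsort(logs)[::-1]
    best = _GENOTYPES[order[0]]
    conf_next = 10.0 * (logs[order[0]] - logs[order[1]])
    homref = _GENOTYPES.index((ref_code, ref_code))
    conf_ref = 10.0 * (logs[order[0]] - logs[homref])
    return best, conf_next, conf_ref


def call_ratio(counts: np.ndarray, reference: str, cfg: CallerConfig | None = None,
               mean_qual: np.ndarray | None = None) -> list[VariantCall]:
    """Allele-ratio caller: het when the minor-base fraction is near 50%
    (>= het_minor_frac), hom when <= max_minor_frac_hom, and no-call with a
    ratio-distortion flag in between — variant sites that do not occur in
    nearly 50 or 100% of reads are ignored rather than called, which is
    what makes this caller blind to chimera-distorted ratios.
    """
    cfg = cfg or CallerConfig()
    totals = counts.sum(axis=0) if counts.ndim == 3 else counts
    L = len(reference)
    ref_codes = encode(reference)
    calls = []
    for pos in range(L):
        c = totals[pos]
        depth = int(c.sum())
        if depth == 0:
            continue
        order = np.argsort(c)[::-1]
        top, second = int(order[0]), int(order[1])
        minor_frac = c[second] / depth
        err = float(_phred_to_err(mean_qual[pos])) if mean_qual is not None else 1e-3
        if minor_frac >= cfg.het_minor_frac:
            gt_codes = tuple(sorted((top, second)))
        elif minor_frac <= cfg.max_minor_frac_hom:
            gt_codes = (top, top)
        else:
            calls.append(VariantCall(pos, reference[pos], None, "ratio",
                                     status="no_call", flags={"ratio_distortion"}))
            continue
        if gt_codes == (ref_codes[pos], ref_codes[pos]):
            continue
        _, _, conf_ref = _likelihood_genotype(c.astype(float), err, ref_codes[pos])
        if conf_ref < cfg.min_qual:
            continue
        gt = tuple(_BASES[b] for b in gt_codes)
        calls.append(VariantCall(pos, reference[pos], gt, "ratio", qual=conf_ref))
    return calls


def call_likelihood(counts: np.ndarray, reference: str,
                    cfg: CallerConfig | None = None,
                    mean_qual: np.ndarray | None = None) -> list[VariantCall]:
    """Diploid genotype-likelihood caller (error probability from Phred
    quality, uniform prior over unordered base pairs). Supports genotypes
    where both bases differ from the reference; calls with Phred-scaled
    confidence below ``min_qual`` are suppressed.
    """
    cfg = cfg or CallerConfig()
    totals = counts.sum(axis=0) if counts.ndim == 3 else counts
    ref_codes = encode(reference)
    calls = []
    for pos in range(len(reference)):
        c = totals[pos].astype(float)
        if c.sum() == 0:
            continue
        err = float(_phred_to_err(mean_qual[pos])) if mean_qual is not None else 1e-3
        best, conf_next, conf_ref = _likelihood_genotype(c, err, ref_codes[pos])
        if best == (ref_codes[pos], ref_codes[pos]):
            continue
        if min(conf_next, conf_ref) < cfg.min_qual:
            continue
        gt = tuple(_BASES[b] for b in best)
        calls.append(VariantCall(pos, reference[pos], gt, "likelihood",
                                 qual=min(conf_next, conf_ref)))
    return calls


# ---------------------------------------------------------------------------
# Haplotype clusters and chimera detection
# ---------------------------------------------------------------------------

def haplotype_clusters(aligned: AlignedSample, sites: list[int],
                       cfg: CallerConfig | None = None,
                       row_mask: np.ndarray | None = None):
    """Cluster reads by their bases at ``sites``; return dominant patterns.

    Returns (patterns, counts, membership) with patterns sorted by
    descending support; only clusters holding >= cluster_frac of the usable
    reads are kept. ``membership`` maps pattern -> boolean row mask over the
    full read matrix.
    """
    cfg = cfg or CallerConfig()
    if not sites:
        return [], [], {}
    mat = aligned.base_matrix
    rows = np.arange(mat.shape[0]) if row_mask is None else np.nonzero(row_mask)[0]
    sub = mat[np.ix_(rows, np.asarray(sites))]
    usable = (sub < 4).all(axis=1)
    sub = sub[usable]
    rows = rows[usable]
    if not len(sub):
        return [], [], {}
    patterns, inverse, counts = np.unique(sub, axis=0, return_inverse=True,
                                          return_counts=True)
    keep = counts >= max(1, cfg.cluster_frac * len(sub))
    order = np.argsort(counts)[::-1]
    order = [k for k in order if keep[k]]
    out_patterns, out_counts, membership = [], [], {}
    for k in order:
        pat = "".join(_BASES[b] for b in patterns[k])
        out_patterns.append(pat)
        out_counts.append(int(counts[k]))
        mask = np.zeros(mat.shape[0], dtype=bool)
        mask[rows[inverse == k]] = True
        membership[pat] = mask
    return out_patterns, out_counts, membership


def detect_chimeric_haplotypes(patterns: list[str], counts: list[int]) -> dict[str, str]:
    """Classify dominant haplotype clusters as chimeric or not.

    With A and B the two largest clusters, a further cluster C is chimeric
    iff some crossover index k makes C equal to A before k and B at/after k
    (or vice versa) — the single-crossover template-switching signature.
    Returns pattern -> verdict ("parental" | "chimeric" | "negative" |
    "indeterminate").
    """
    verdicts: dict[str, str] = {}
    if len(patterns) < 3:
        return {p: "parental" for p in patterns[:2]}
    n_sites = len(patterns[0])
    a, b = patterns[0], patterns[1]
    verdicts[a] = verdicts[b] = "parental"
    for c in patterns[2:]:
        if n_sites < 2:
            verdicts[c] = "indeterminate"
            continue
        chim = any(
            (c[:k] == x[:k] and c[k:] == y[k:])
            for k in range(1, n_sites)
            for x, y in ((a, b), (b, a))
        )
        verdicts[c] = "chimeric" if chim else "negative"
    return verdicts


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def _cluster_supports(pos: int, base: str, sites: list[int], patterns: list[str]) -> bool:
    if pos not in sites:
        return False
    i = sites.index(pos)
    return any(p[i] == base for p in patterns)


def _strand_fracs(counts: np.ndarray, pos: int, code: int):
    """Per-strand fraction of ``code`` at ``pos``; (frac_fwd, frac_rev, cov_fwd, cov_rev)."""
    cf, cr = counts[0, pos], counts[1, pos]
    nf, nr = cf.sum(), cr.sum()
    ff = cf[code] / nf if nf else 0.0
    fr = cr[code] / nr if nr else 0.0
    return ff, fr, int(nf), int(nr)


def reconcile_calls(ratio_calls: list[VariantCall], lik_calls: list[VariantCall],
                    counts: np.ndarray, dels: np.ndarray, reference: str,
                    homopolymer: np.ndarray, cluster_patterns: list[str],
                    cluster_sites: list[int], cfg: CallerConfig | None = None,
                    mean_qual: np.ndarray | None = None
                    ) -> tuple[list[VariantCall], list[str]]:
    """Merge the two call sets through the error-class taxonomy.

    Concordant calls pass through; disagreements are classified and resolved
    by evidence rules (see module docstring). Chimera handling happens
    upstream (cluster removal + rerun); here the remaining four classes are
    applied per site. A disagreement matched by no rule is flagged for
    manual review and the sample is not genotyped at that site.
    """
    cfg = cfg or CallerConfig()
    ref_codes = encode(reference)
    by_pos_r = {c.pos: c for c in ratio_calls}
    by_pos_l = {c.pos: c for c in lik_calls}
    totals = counts.sum(axis=0)
    final: list[VariantCall] = []
    notes: list[str] = []

    for pos in sorted(set(by_pos_r) | set(by_pos_l)):
        r, l = by_pos_r.get(pos), by_pos_l.get(pos)
        r_gt = r.genotype if r else None
        l_gt = l.genotype if l else None
        depth = totals[pos].sum()
        ref_b = reference[pos]

        if r is not None and l is not None and r_gt == l_gt and r_gt is not None:
            final.append(VariantCall(pos, ref_b, r_gt, "both",
                                     qual=min(r.qual or 0, l.qual or 0),
                                     status="concordant"))
            continue

        # -- strand_bias_misalignment: single-strand support, clean opposite
        candidate = l_gt or r_gt
        strand_flagged = False
        if candidate is not None:
            for b in set(candidate) - {ref_b}:
                ff, fr, nf, nr = _strand_fracs(counts, pos, _BASES.index(b))
                one_strand = (
                    (ff >= cfg.min_minor_frac and fr <= cfg.max_minor_frac_hom and nr >= cfg.strand_min_cov)
                    or (fr >= cfg.min_minor_frac and ff <= cfg.max_minor_frac_hom and nf >= cfg.strand_min_cov)
                )
                if one_strand:
                    strand_flagged = True
        if not strand_flagged and (dels[0, pos] or dels[1, pos]):
            dn_f, dn_r = int(dels[0, pos]), int(dels[1, pos])
            nf, nr = counts[0, pos].sum(), counts[1, pos].sum()
            if (dn_f and not dn_r and nr >= cfg.strand_min_cov) or \
               (dn_r and not dn_f and nf >= cfg.strand_min_cov):
                strand_flagged = True
        if strand_flagged:
            # recompute from the strand without the artefact
            dn_f, dn_r = int(dels[0, pos]), int(dels[1, pos])
            clean_strand = 0 if (dn_r or counts[1, pos].sum() == 0) else 1
            if candidate is not None:
                # prefer the strand lacking the suspicious base support
                for b in set(candidate) - {ref_b}:
                    ff, fr, nf2, nr2 = _strand_fracs(counts, pos, _BASES.index(b))
                    clean_strand = 1 if ff > fr else 0
            c_clean = counts[clean_strand, pos].astype(float)
            if c_clean.sum() == 0:
                final.append(VariantCall(pos, ref_b, None, "both",
                                         status="rejected:strand_bias_misalignment"))
                notes.append(f"pos {pos}: strand-biased, no clean coverage")
                continue
            err = float(_phred_to_err(mean_qual[pos])) if mean_qual is not None else 1e-3
            best, _, conf_ref = _likelihood_genotype(c_clean, err, ref_codes[pos])
            gt = tuple(_BASES[b] for b in best)
            status = "reconciled:strand_bias_misalignment"
            if best == (ref_codes[pos], ref_codes[pos]):
                final.append(VariantCall(pos, ref_b, gt, "both", qual=conf_ref,
                                         status="rejected:strand_bias_misalignment"))
            else:
                final.append(VariantCall(pos, ref_b, gt, "both", qual=conf_ref,
                                         status=status))
            notes.append(f"pos {pos}: strand_bias_misalignment resolved on "
                         f"{'+' if clean_strand == 0 else '-'} strand")
            continue

        # -- sequencing_error: likelihood-only call with tiny minor fraction
        if l_gt is not None and (r is None or r_gt is None or not _gt_variant(r_gt, ref_b)):
            minor = _minor_frac(totals[pos], l_gt, ref_b)
            supported = any(
                _cluster_supports(pos, b, cluster_sites, cluster_patterns)
                for b in set(l_gt) - {ref_b}
            )
            if minor < cfg.min_minor_frac and not supported:
                final.append(VariantCall(pos, ref_b, None, "likelihood",
                                         status="rejected:sequencing_error"))
                notes.append(f"pos {pos}: likelihood-only call at minor fraction "
                             f"{minor:.3f} rejected as sequencing error")
                continue

        # -- tri_allelic: both-non-reference genotype from likelihood caller
        if l_gt is not None and all(b != ref_b for b in l_gt):
            final.append(VariantCall(pos, ref_b, l_gt, "likelihood",
                                     qual=l.qual, status="reconciled:tri_allelic"))
            notes.append(f"pos {pos}: tri_allelic genotype {l_gt} accepted")
            continue

        # -- homopolymer: ratio call in homopolymer context, strand-consistent
        if r_gt is not None and homopolymer[pos]:
            consistent = True
            for b in set(r_gt) - {ref_b}:
                ff, fr, nf, nr = _strand_fracs(counts, pos, _BASES.index(b))
                lo = cfg.min_minor_frac if r.genotype[0] != r.genotype[1] else 1 - cfg.max_minor_frac_hom
                if (nf and ff < lo * 0.5) or (nr and fr < lo * 0.5):
                    consistent = False
            if consistent:
                final.append(VariantCall(pos, ref_b, r_gt, "ratio", qual=r.qual,
                                         status="reconciled:homopolymer"))
                notes.append(f"pos {pos}: homopolymer-context variant kept from ratio caller")
                continue

        # -- ratio-only call with strong support (likelihood suppressed), or
        #    one caller silent: accept the supported genotype when fractions
        #    put it unambiguously in band.
        chosen = None
        for cand, src in ((r, "ratio"), (l, "likelihood")):
            if cand is not None and cand.genotype is not None:
                minor = _minor_frac(totals[pos], cand.genotype, ref_b)
                het = cand.genotype[0] != cand.genotype[1]
                if (het and minor >= cfg.min_minor_frac) or \
                   (not het and minor >= 1 - cfg.max_minor_frac_hom):
                    chosen = (cand, src)
                    break
        if chosen is not None:
            cand, src = chosen
            final.append(VariantCall(pos, ref_b, cand.genotype, src,
                                     qual=cand.qual, status=f"reconciled:{src}_supported"))
            continue

        final.append(VariantCall(pos, ref_b, None, "both", status="manual_review",
                                 flags={"unresolved"}))
        notes.append(f"pos {pos}: unresolvable disagreement, flagged for manual review")

    # Final support guarantee: every non-reference genotype base must be
    # seen in at least min_minor_frac of post-filter reads.
    checked = []
    for call in final:
        if call.genotype is not None and call.is_variant():
            ok = True
            for b in set(call.genotype) - {call.ref}:
                frac = totals[call.pos][_BASES.index(b)] / max(1, totals[call.pos].sum())
                if frac < cfg.min_minor_frac:
                    ok = False
            if not ok and not call.status.startswith("reconciled:strand_bias"):
                checked.append(VariantCall(call.pos, call.ref, None, call.caller,
                                           status="rejected:sequencing_error"))
                notes.append(f"pos {call.pos}: genotype support below minor-fraction floor")
                continue
        checked.append(call)
    return checked, notes


def _gt_variant(gt: tuple[str, str], ref_b: str) -> bool:
    return any(b != ref_b for b in gt)


def _minor_frac(counts4: np.ndarray, gt: tuple[str, str], ref_b: str) -> float:
    depth = counts4.sum()
    if depth == 0:
        return 0.0
    fracs = [counts4[_BASES.index(b)] / depth for b in set(gt) - {ref_b}]
    return min(fracs) if fracs else 0.0


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

def phase_haplotypes(aligned: AlignedSample, final_calls: list[VariantCall],
                     cfg: CallerConfig | None = None,
                     row_mask: np.ndarray | None = None,
                     chimera_removed: int = 0) -> PhasedPair:
    """Cluster reads by their bases at heterozygous sites and splice the two
    cluster consensuses onto the reference.

    The top consistent pattern fixes one haplotype; its complement (forced
    site-by-site by the genotypes, including at tri-allelic columns) fixes
    the other. Homozygous samples return two identical sequences. Competing
    phasings within ``phase_ambiguity_frac`` of the chosen one raise
    :class:`PhaseAmbiguousError`.
    """
    cfg = cfg or CallerConfig()
    reference = aligned.reference
    variants = [c for c in final_calls if c.genotype is not None and c.is_variant()]
    het = [c for c in variants if c.is_het()]
    hom = [c for c in variants if not c.is_het()]

    base = list(reference)
    for c in hom:
        base[c.pos] = c.genotype[0]

    if not het:
        n = aligned.base_matrix.shape[0] if row_mask is None else int(row_mask.sum())
        hap = "".join(base)
        return PhasedPair((hap, hap), (n, n), chimera_removed)

    sites = [c.pos for c in het]
    genotypes = {c.pos: set(c.genotype) for c in het}
    patterns, counts, _ = haplotype_clusters(aligned, sites, cfg, row_mask)
    consistent = [
        (p, n) for p, n in zip(patterns, counts)
        if all(p[i] in genotypes[pos] for i, pos in enumerate(sites))
    ]
    if not consistent:
        raise PhaseAmbiguousError("phase_ambiguous: no read cluster matches the genotypes")
    p1, n1 = consistent[0]
    comp = "".join(
        (genotypes[pos] - {p1[i]}).pop() for i, pos in enumerate(sites)
    )
    n2 = dict(consistent).get(comp, 0)
    rivals = [n for p, n in consistent if p not in (p1, comp)]
    if n2 == 0 or (rivals and max(rivals) >= (1 - cfg.phase_ambiguity_frac) * n2):
        raise PhaseAmbiguousError("phase_ambiguous: competing phasings within support band")
    h1, h2 = list(base), list(base)
    for i, pos in enumerate(sites):
        h1[pos] = p1[i]
        h2[pos] = comp[i]
    return PhasedPair(("".join(h1), "".join(h2)), (n1, n2), chimera_removed)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def call_sample(reads: list[SeqRead], reference: str, sample: str = "sample",
                cfg: CallerConfig | None = None) -> SampleCallSet:
    """Full per-sample pipeline: align, dual-call, de-chimerise, reconcile,
    phase. Returns the complete :class:`SampleCallSet`."""
    cfg = cfg or CallerConfig()
    aligned = align_reads(reads, reference, cfg)
    counts, dels = aligned.pileup_arrays()
    ratio = call_ratio(counts, reference, cfg, aligned.mean_qual)
    lik = call_likelihood(counts, reference, cfg, aligned.mean_qual)

    sites = sorted({c.pos for c in ratio + lik})
    patterns, pcounts, membership = haplotype_clusters(aligned, sites, cfg)
    verdicts = detect_chimeric_haplotypes(patterns, pcounts)
    chimeric = [p for p, v in verdicts.items() if v == "chimeric"]
    row_mask = np.ones(aligned.base_matrix.shape[0], dtype=bool)
    notes: list[str] = []
    if chimeric:
        for p in chimeric:
            row_mask &= ~membership[p]
        notes.append(f"chimera: removed {len(chimeric)} recombinant cluster(s); callers rerun")
        counts, dels = aligned.pileup_arrays(row_mask)
        ratio = call_ratio(counts, reference, cfg, aligned.mean_qual)
        lik = call_likelihood(counts, reference, cfg, aligned.mean_qual)
        sites = sorted({c.pos for c in ratio + lik})
        patterns, pcounts, membership = haplotype_clusters(aligned, sites, cfg, row_mask)

    final, rec_notes = reconcile_calls(
        ratio, lik, counts, dels, reference, aligned.homopolymer,
        patterns, sites, cfg, aligned.mean_qual,
    )
    if chimeric:
        for call in final:
            if call.genotype is not None and call.is_variant():
                call.flags.add("chimera_filtered")
    notes.extend(rec_notes)
    try:
        phased = phase_haplotypes(aligned, final, cfg, row_mask, len(chimeric))
    except PhaseAmbiguousError as exc:
        notes.append(str(exc))
        phased = None
    return SampleCallSet(
        sample=sample, final_calls=final, ratio_calls=ratio,
        likelihood_calls=lik, phased=phased,
        n_reads_used=int(row_mask.sum()), n_reads_discarded=aligned.n_discarded,
        reconciliation_notes=notes,
    )
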