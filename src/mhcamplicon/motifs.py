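"""Promoter motif scanning, tandem-duplication detection and column entropy.

MHC class II proximal promoters (~150-200 bp upstream of the transcription
start) carry conserved W/S, X1/X2 and Y boxes; DQA additionally carries
NF-kB and T boxes and DQB a TTAA box. Motif consensus sequences and their
expected windows ship as an editable config table (they are data, seeded
from model-species promoter literature, not code). Scanning is a
position-complete Hamming-distance window scan on the coding strand, so
motif duplications surface as multiple hits of the same motif.

The tandem-duplication detector finds repeated units of 11-22 bp whose
copies are separated by short spacers — the pattern of the promoter
duplications this toolkit was built to study (an 11-bp unit repeated three
times, and a complete 14-bp T-box copy adding a net 18 bp insertion).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

log = logging.getLogger("mhcamplicon")


@dataclass
class MotifDef:
    name: str
    locus: str                       # DQA | DQB | DRA | DRB | ALL
    consensus: str
    max_mismatches: int = 2
    window: tuple[int, int] | None = None  # bp upstream of the TSS (seq 3' end)

    def __post_init__(self):
        if len(self.consensus) < 4:
            raise ValueError(f"motif {self.name}: consensus shorter than 4 bp")
        if self.window is not None:
            lo, hi = self.window
            if not (0 <= lo < hi <= 200):
                raise ValueError(f"motif {self.name}: window must sit within 200 bp upstream")


@dataclass
class MotifHit:
    motif: str
    start: int                       # 0-based on the scanned sequence
    mismatches: int
    matched: str
    strand: str = "+"


@dataclass
class DuplicationReport:
    unit: str
    unit_length: int
    copy_count: int
    starts: list[int]
    spacers: list[int]
    contained_motif: str | None = None
    net_insertion: int | None = None


def load_motif_defs(path=None) -> list[MotifDef]:
    """Read motif definitions from TSV (locus, motif, consensus, window_start,
    window_end, max_mm). Window bounds count bp upstream from the sequence
    3' end (the transcription start); blank = scan the whole sequence."""
    if path is None:
        path = resources.files("mhcamplicon") / "data" / "motifs.tsv"
    defs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("locus\t"):
                continue
            locus, name, consensus, w0, w1, mm = line.split("\t")[:6]
            window = (int(w0), int(w1)) if w0 and w1 else None
            defs.append(MotifDef(name=name, locus=locus, consensus=consensus.upper(),
                                 max_mismatches=int(mm), window=window))
    return defs


def defs_for_locus(defs: list[MotifDef], locus: str) -> list[MotifDef]:
    return [d for d in defs if d.locus in (locus, "ALL")]


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_motifs(sequence: str, defs: list[MotifDef]) -> list[MotifHit]:
    """All substrings within each motif's window at Hamming distance <=
    max_mismatches, coding strand only. Overlapping hits of one motif are
    reported separately so duplications appear as multiple hits.
    """
    sequence = sequence.upper()
    L = len(sequence)
    hits: list[MotifHit] = []
    for d in defs:
        m = len(d.consensus)
        if m > L:
            log.warning("sequence shorter than motif %s; skipped", d.name)
            continue
        if d.window is None:
            lo, hi = 0, L - m
        else:
            # window counts bp upstream of the TSS at the sequence 3' end
            up_lo, up_hi = d.window
            lo, hi = max(0, L - up_hi), min(L - m, L - up_lo - m)
            if hi < lo:
                log.warning("sequence shorter than window of motif %s", d.name)
                continue
        for start in range(lo, hi + 1):
            mm = _hamming(sequence[start:start + m], d.consensus)
            if mm <= d.max_mismatches:
                hits.append(MotifHit(motif=d.name, start=start, mismatches=mm,
                                     matched=sequence[start:start + m]))
    return hits


# ---------------------------------------------------------------------------
# Tandem duplications
# ---------------------------------------------------------------------------

def detect_tandem_duplications(sequence: str, min_unit: int = 11,
                               max_unit: int = 22, max_spacer: int = 30,
                               motif_defs: list[MotifDef] | None = None,
                               reference: str | None = None
                               ) -> list[DuplicationReport]:
    """Find maximal repeated units with copies separated by short spacers.

    Units are searched greedily from ``max_unit`` down to ``min_unit``;
    each exact copy chain (spacers <= ``max_spacer``) becomes one report,
    and spans already explained by a longer unit are not re-reported. When
    ``motif_defs`` is given the report names any catalogued motif contained
    in the unit; ``reference`` (the unduplicated homolog) adds the net
    inserted length.
    """
    sequence = sequence.upper()
    L = len(sequence)

    # collect every maximal copy chain for every admissible unit length
    candidates: list[tuple[int, list[int]]] = []
    seen: set[tuple[int, tuple[int, ...]]] = set()
    for u in range(max_unit, min_unit - 1, -1):
        for i in range(L - 2 * u + 1):
            unit = sequence[i:i + u]
            starts = [i]
            pos = i + u
            while True:
                nxt = sequence.find(unit, pos, pos + max_spacer + u)
                if nxt == -1 or nxt - pos > max_spacer:
                    break
                starts.append(nxt)
                pos = nxt + u
            if len(starts) >= 2:
                key = (u, tuple(starts))
                if key not in seen:
                    seen.add(key)
                    candidates.append((u, starts))

    # prefer chains explaining more copies, then longer units
    candidates.sort(key=lambda c: (-len(c[1]), -c[0], c[1][0]))
    reports: list[DuplicationReport] = []
    covered = np.zeros(L, dtype=bool)
    for u, starts in candidates:
        if any(covered[s:s + u].any() for s in starts):
            continue
        unit = sequence[starts[0]:starts[0] + u]
        spacers = [starts[k + 1] - (starts[k] + u) for k in range(len(starts) - 1)]
        contained = None
        if motif_defs:
            for d in motif_defs:
                m = len(d.consensus)
                if m <= u and any(
                    _hamming(unit[s:s + m], d.consensus) <= d.max_mismatches
                    for s in range(u - m + 1)
                ):
                    contained = d.name
                    break
        reports.append(DuplicationReport(
            unit=unit, unit_length=u, copy_count=len(starts),
            starts=starts, spacers=spacers, contained_motif=contained,
            net_insertion=(L - len(reference)) if reference is not None else None,
        ))
        for s in starts:
            covered[s:s + u] = True
    reports.sort(key=lambda r: r.starts[0])
    return reports


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

@dataclass
class EntropyProfile:
    entropy: np.ndarray              # per-column H in bits (nan = masked)
    coverage: np.ndarray             # non-gap rows per column
    gap_mode: str

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tH\tcoverage\n")
            for i, (h, c) in enumerate(zip(self.entropy, self.coverage)):
                fh.write(f"{i + 1}\t{'' if math.isnan(h) else f'{h:.4f}'}\t{int(c)}\n")


def column_entropy(rows: list[str], gap_mode: str = "exclude") -> EntropyProfile:
    """Per-column Shannon entropy H = -sum p log2 p of an alignment.

    ``gap_mode="exclude"`` renormalises over non-gap states (H <= 2 bits);
    ``"fifth-state"`` treats '-' as a fifth character (H <= log2 5).
    Columns that are entirely gaps are masked (NaN).
    """
    if gap_mode not in ("exclude", "fifth-state"):
        raise ValueError("gap_mode must be 'exclude' or 'fifth-state'")
    rows = [r.upper() for r in rows]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows differ in length")
    L = len(rows[0])
    H = np.full(L, np.nan)
    coverage = np.zeros(L, dtype=int)
    for j in range(L):
        col = [r[j] for r in rows]
        coverage[j] = sum(c != "-" for c in col)
        if gap_mode == "exclude":
            col = [c for c in col if c != "-"]
        if not col:
            continue  # all-gap column stays masked
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        H[j] = float(-(p * np.log2(p)).sum())
    return EntropyProfile(entropy=H, coverage=coverage, gap_mode=gap_mode)
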