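"""Coding-region analyses for the peptide binding region (PBR).

Covers partial-codon trimming and translation, the variable-site census,
binding-pocket enrichment tests (G and chi-square goodness-of-fit),
transition/transversion bias, pairwise dN:dS by Nei–Gojobori counting (with
an optional transition/transversion-weighted site-counting variant),
codon-usage statistics (RSCU, Wright's effective number of codons Nc,
Bennetzen–Hall codon bias index CBI, GC fraction) and an approximate
counting-based per-codon selection scan.

Both MHC class II exon-2 amplicons begin and end mid-codon (a codon starts
on exon 1 and finishes on exon 2), so the first two and the last nucleotide
are trimmed before any codon-level analysis: a 249-nt DQA exon yields 82
complete codons, a 270-nt DQB exon yields 89.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

log = logging.getLogger("mhcamplicon")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE[codon]


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


# ---------------------------------------------------------------------------
# Coding alignment
# ---------------------------------------------------------------------------

@dataclass
class CodingAlignment:
    locus: str
    names: list[str]
    nucleotides: list[str]            # in-frame, post-trim
    peptides: list[str]
    variable_nt_columns: list[int]    # 0-based
    variable_aa_columns: list[int]    # 0-based

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides[0]) // 3


def exon_to_peptides(sequences, names=None, locus: str = "locus",
                     trim: tuple[int, int] = (2, 1)) -> CodingAlignment:
    """Trim the partial codon (first two and last base by default),
    translate, and census variable columns. Raises if the post-trim length
    is not divisible by 3; stop-bearing alleles are flagged via warning.
    """
    sequences = list(sequences)
    if len({len(s) for s in sequences}) > 1:
        raise ValueError("alleles must be equal length")
    head, tail = trim
    trimmed = [s[head:len(s) - tail].upper() for s in sequences]
    if len(trimmed[0]) % 3:
        raise ValueError(
            f"post-trim length {len(trimmed[0])} not divisible by 3"
        )
    peptides = [str(Seq(s).translate()) for s in trimmed]
    for name, pep in zip(names or range(len(peptides)), peptides):
        if "*" in pep:
            log.warning("allele %s translation contains a stop codon", name)
    nt_cols = [j for j in range(len(trimmed[0]))
               if len({s[j] for s in trimmed}) > 1]
    aa_cols = [j for j in range(len(peptides[0]))
               if len({p[j] for p in peptides}) > 1]
    return CodingAlignment(
        locus=locus,
        names=list(names) if names else [f"a{i}" for i in range(len(sequences))],
        nucleotides=trimmed, peptides=peptides,
        variable_nt_columns=nt_cols, variable_aa_columns=aa_cols,
    )


# ---------------------------------------------------------------------------
# Binding-pocket enrichment
# ---------------------------------------------------------------------------

@dataclass
class PocketMask:
    locus: str
    positions: set[int]               # 1-based amino-acid positions
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.positions)


_EXPECTED_MASK_SIZES = {"DQA": 15, "DQB": 19}


def load_pocket_masks(path=None) -> dict[str, PocketMask]:
    """Read pocket masks from a TSV (locus, pocket, position). The shipped
    defaults are validated against the printed totals (15 DQA, 19 DQB)."""
    if path is None:
        path = resources.files("mhcamplicon") / "data" / "pockets.tsv"
        default = True
    else:
        default = False
    masks: dict[str, PocketMask] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("locus\t"):
                continue
            locus, pocket, pos = line.split("\t")[:3]
            mask = masks.setdefault(locus, PocketMask(locus, set()))
            p = int(pos)
            if p in mask.positions:
                raise ValueError(f"duplicate pocket position {locus}:{p}")
            mask.positions.add(p)
            mask.labels[p] = pocket
    if default:
        for locus, expected in _EXPECTED_MASK_SIZES.items():
            if locus in masks and masks[locus].size != expected:
                raise ValueError(
                    f"default {locus} mask has {masks[locus].size} positions, expected {expected}"
                )
    return masks


@dataclass
class EnrichmentResult:
    g: float
    chi2: float
    dof: int
    p_g: float
    p_chi2: float
    observed: tuple[int, int]         # (in-pocket, out-of-pocket)
    expected: tuple[float, float]


def pocket_enrichment_test(variable_positions, mask: PocketMask, total_aa: int,
                           williams: bool = False) -> EnrichmentResult:
    """Two-cell goodness-of-fit of variable-site counts against class sizes.

    Cells are (in-pocket, out-of-pocket) counts of variable amino-acid
    positions; expected counts are proportional to the pocket / non-pocket
    class sizes. G = 2 sum O ln(O/E) with zero cells contributing 0; the
    chi-square analogue is reported alongside. ``williams`` applies the
    Williams small-sample correction to G.
    """
    positions = set(int(p) for p in variable_positions)
    if not positions:
        return EnrichmentResult(0.0, 0.0, 1, 1.0, 1.0, (0, 0), (0.0, 0.0))
    if any(p < 1 or p > total_aa for p in positions):
        raise ValueError("variable positions outside [1, total_aa]")
    if any(p < 1 or p > total_aa for p in mask.positions):
        raise ValueError("mask positions outside [1, total_aa]")
    n_in = len(positions & mask.positions)
    n_var = len(positions)
    obs = np.array([n_in, n_var - n_in], dtype=float)
    exp = n_var * np.array([mask.size, total_aa - mask.size]) / total_aa
    nz = obs > 0
    g = 2.0 * float((obs[nz] * np.log(obs[nz] / exp[nz])).sum())
    if williams:
        q = 1.0 + (2 * 2 - 1) / (6.0 * n_var * (2 - 1))  # k=2 cells
        g /= q
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = 1
    return EnrichmentResult(
        g=g, chi2=chi2, dof=dof,
        p_g=float(stats.chi2.sf(g, dof)), p_chi2=float(stats.chi2.sf(chi2, dof)),
        observed=(n_in, n_var - n_in), expected=(float(exp[0]), float(exp[1])),
    )


# ---------------------------------------------------------------------------
# Transition/transversion bias
# ---------------------------------------------------------------------------

def titv_ratio(sequences, min_sites_for_k2p: int = 1, method: str = "auto") -> dict:
    """Transition/transversion rate-ratio estimate R averaged over pairs.

    Primary estimator: K2P-style, R = s/v with s and v the corrected
    transition and transversion distances. When a pair's distances are too
    small (or the K2P logs are undefined), or ``method="counting"`` is
    forced, a direct counting estimate R = transitions/transversions over
    all pairs is used. Under random substitution R = 0.5 (4 transition vs
    8 transversion types).
    """
    if method not in ("auto", "k2p", "counting"):
        raise ValueError("method must be auto, k2p or counting")
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need >= 2 alleles")
    ratios = []
    ts_total = tv_total = 0
    for a, b in itertools.combinations(seqs, 2):
        ts = tv = 0
        for x, y in zip(a, b):
            if x == y:
                continue
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
        ts_total += ts
        tv_total += tv
        if method == "counting":
            continue
        n = len(a)
        P, Q = ts / n, tv / n
        if ts + tv < min_sites_for_k2p:
            continue
        if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
            continue
        s = -0.5 * math.log(1 - 2 * P - Q) + 0.25 * math.log(1 - 2 * Q)
        v = -0.5 * math.log(1 - 2 * Q)
        if v > 0:
            ratios.append(s / v)
    if ratios:
        return {"R": float(np.mean(ratios)), "method": "k2p",
                "transitions": ts_total, "transversions": tv_total}
    if tv_total == 0:
        return {"R": math.inf if ts_total else math.nan, "method": "counting",
                "undefined": True,
                "transitions": ts_total, "transversions": tv_total}
    return {"R": ts_total / tv_total, "method": "counting",
            "transitions": ts_total, "transversions": tv_total}


# ---------------------------------------------------------------------------
# Nei–Gojobori dN/dS
# ---------------------------------------------------------------------------

def syn_fraction(codon: str, position: int, kappa: float | None = None) -> float:
    """Fraction of possible changes at ``position`` that are synonymous.

    Changes producing a stop codon count as nonsynonymous. With ``kappa``
    the three alternatives are weighted (transitions x kappa, transversions
    x 1) instead of equally.
    """
    aa = translate_codon(codon)
    num = den = 0.0
    for b in "ACGT":
        if b == codon[position]:
            continue
        w = (kappa if kappa is not None and is_transition(codon[position], b) else 1.0)
        den += w
        mutant = codon[:position] + b + codon[position + 1:]
        if mutant not in _STOPS and translate_codon(mutant) == aa:
            num += w
    return num / den


def codon_sites(codon: str, kappa: float | None = None) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon (sum = 3)."""
    s = sum(syn_fraction(codon, p, kappa) for p in range(3))
    return s, 3.0 - s


def codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts between two codons with equal-path
    averaging; paths passing through a stop codon are excluded (all-stop
    path sets fall back to including them)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0

    def walk(order):
        cur = c1
        sd = nd = 0.0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in _STOPS:
                return None
            sd_step = 1.0 if translate_codon(nxt) == translate_codon(cur) else 0.0
            sd += sd_step
            nd += 1.0 - sd_step
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff)]
    valid = [r for r in results if r is not None]
    if not valid:  # degenerate: every path crosses a stop; average them all
        def walk_any(order):
            cur = c1
            sd = nd = 0.0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                same = (translate_codon(nxt) if nxt not in _STOPS else "*") == \
                       (translate_codon(cur) if cur not in _STOPS else "*")
                sd += 1.0 if same else 0.0
                nd += 0.0 if same else 1.0
                cur = nxt
            return sd, nd
        valid = [walk_any(order) for order in itertools.permutations(diff)]
    sd = float(np.mean([v[0] for v in valid]))
    nd = float(np.mean([v[1] for v in valid]))
    return sd, nd


def _jc_correct(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


@dataclass
class SelectionResult:
    mean_dn: float
    mean_ds: float
    omega: float | None               # None when dS = 0 (undefined, not inf)
    pairs: pd.DataFrame
    titv_R: float | None
    method: str                       # "NG86" | "tstv-weighted"

    @property
    def omega_undefined(self) -> bool:
        return self.omega is None


def pairwise_dnds(alignment: CodingAlignment, method: str = "NG86") -> SelectionResult:
    """Pairwise dN and dS over all allele pairs with Jukes–Cantor correction.

    ``method="NG86"`` uses equal-weight site counting; ``"tstv-weighted"``
    weights site counting by the estimated transition/transversion ratio R
    (kappa = R / 0.5). The summary ratio w is mean dN / mean dS over pairs;
    w is flagged undefined (None) when mean dS = 0.
    """
    seqs = alignment.nucleotides
    if len(seqs) < 2:
        raise ValueError("need >= 2 alleles")
    kappa = None
    titv = None
    if method == "tstv-weighted":
        titv = titv_ratio(seqs)
        R = titv["R"]
        kappa = max(1e-6, (R / 0.5)) if math.isfinite(R) else None
    elif method != "NG86":
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(seqs), 2):
        S = N = Sd = Nd = 0.0
        for k in range(0, len(a), 3):
            c1, c2 = a[k:k + 3], b[k:k + 3]
            s1, n1 = codon_sites(c1, kappa)
            s2, n2 = codon_sites(c2, kappa)
            S += (s1 + s2) / 2
            N += (n1 + n2) / 2
            sd, nd = codon_path_counts(c1, c2)
            Sd += sd
            Nd += nd
        ps = Sd / S if S else 0.0
        pn = Nd / N if N else 0.0
        rows.append({
            "a": alignment.names[i], "b": alignment.names[j],
            "S": S, "N": N, "Sd": Sd, "Nd": Nd,
            "dS": _jc_correct(ps), "dN": _jc_correct(pn),
        })
    table = pd.DataFrame(rows)
    dn_vals = table["dN"].dropna()
    ds_vals = table["dS"].dropna()
    mean_dn = float(dn_vals.mean()) if len(dn_vals) else math.nan
    mean_ds = float(ds_vals.mean()) if len(ds_vals) else math.nan
    omega = (mean_dn / mean_ds) if (mean_ds and not math.isnan(mean_ds)
                                    and mean_ds > 0 and not math.isnan(mean_dn)) else None
    return SelectionResult(
        mean_dn=mean_dn, mean_ds=mean_ds, omega=omega, pairs=table,
        titv_R=(titv or {}).get("R"), method=method,
    )


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

_FAMILIES: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.items():
    _FAMILIES.setdefault(aa, []).append(codon)


@dataclass
class CodonUsageStats:
    rscu: dict[str, float]
    cbi: float
    nc: float
    gc: float
    optimal_codons: dict[str, str]


def _codon_counts(sequences) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in sequences:
        if len(seq) % 3:
            raise ValueError("sequences must be in frame")
        for k in range(0, len(seq), 3):
            codon = seq[k:k + 3]
            if codon in _STOPS:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_usage(sequences, optimal_codons: dict[str, str] | None = None) -> CodonUsageStats:
    """RSCU, Wright's Nc, Bennetzen–Hall CBI and GC fraction.

    RSCU is observed use relative to uniform synonymous use (unused family
    -> 0). Nc uses Wright's F-hat per amino acid averaged within degeneracy
    classes (2-, 3-, 4-, 6-fold), substituting a missing class mean by the
    mean of the observed classes (logged); clamped to [20, 61]. CBI scores
    usage of "optimal" codons — by default the most frequent codon per
    amino acid within the analysed set, mirroring the DnaSP convention.
    """
    counts = _codon_counts(sequences)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no codons")

    rscu: dict[str, float] = {}
    for aa, family in _FAMILIES.items():
        fam_total = sum(counts.get(c, 0) for c in family)
        for c in family:
            rscu[c] = (len(family) * counts.get(c, 0) / fam_total) if fam_total else 0.0

    # Wright's Nc over degeneracy classes
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in _FAMILIES.items():
        k = len(family)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        p2 = sum((counts.get(c, 0) / n) ** 2 for c in family)
        F = (n * p2 - 1) / (n - 1)
        if F > 0:
            class_F[k].append(F)
    class_mean = {k: (float(np.mean(v)) if v else None) for k, v in class_F.items()}
    if class_mean[3] is None and class_mean[2] is not None and class_mean[4] is not None:
        class_mean[3] = (class_mean[2] + class_mean[4]) / 2
    observed_means = [m for m in class_mean.values() if m is not None]
    if observed_means:
        fallback = float(np.mean(observed_means))
        for k in class_mean:
            if class_mean[k] is None:
                log.info("Nc: degeneracy class %d-fold absent; substituting class mean", k)
                class_mean[k] = fallback
        nc = 2 + 9 / class_mean[2] + 1 / class_mean[3] + 5 / class_mean[4] + 3 / class_mean[6]
        nc = float(min(61.0, max(20.0, nc)))
    else:
        log.warning("Nc undefined: no amino acid observed more than once")
        nc = float("nan")

    # CBI
    if optimal_codons is None:
        optimal_codons = {}
        for aa, family in _FAMILIES.items():
            if len(family) == 1:
                continue
            optimal_codons[aa] = max(family, key=lambda c: (counts.get(c, 0), c))
    n_tot = sum(counts.get(c, 0) for aa, fam in _FAMILIES.items() if len(fam) > 1 for c in fam)
    n_opt = sum(counts.get(optimal_codons[aa], 0) for aa in optimal_codons)
    n_ran = sum(
        sum(counts.get(c, 0) for c in fam) / len(fam)
        for aa, fam in _FAMILIES.items() if len(fam) > 1
    )
    cbi = (n_opt - n_ran) / (n_tot - n_ran) if n_tot > n_ran else 0.0

    gc = sum(seq.count("G") + seq.count("C") for seq in sequences) / \
        sum(len(seq) for seq in sequences)
    return CodonUsageStats(rscu=rscu, cbi=float(cbi), nc=nc, gc=float(gc),
                           optimal_codons=optimal_codons)


# ---------------------------------------------------------------------------
# Per-site selection scan (counting approximation)
# ---------------------------------------------------------------------------

def site_dnds_scan(alignment: CodingAlignment, alpha: float = 0.05) -> pd.DataFrame:
    """Approximate per-codon selection classes from star-tree parsimony.

    For each codon column, substitutions are counted from every allele to
    the modal codon (equal-path averaging) and the nonsynonymous excess is
    tested against the codon's site-count expectation with a binomial test.
    Output classes mirror a three-way w<1 / w~1 / w>1 display and are an
    explicit approximation of a codon-model site analysis, not a posterior.
    """
    rows = []
    n_codons = alignment.n_codons
    for j in range(n_codons):
        codons = [s[3 * j:3 * j + 3] for s in alignment.nucleotides]
        uniq = set(codons)
        if len(uniq) == 1:
            rows.append({"codon": j + 1, "class": "no signal", "p": 1.0,
                         "nd": 0.0, "sd": 0.0})
            continue
        modal = max(uniq, key=codons.count)
        s_sites, n_sites = codon_sites(modal)
        nd = sd = 0.0
        for c in codons:            # every allele contributes its changes
            if c == modal:
                continue
            csd, cnd = codon_path_counts(modal, c)
            sd += csd
            nd += cnd
        n_changes = int(round(nd + sd))
        p_nonsyn = n_sites / 3.0
        if n_changes == 0:
            rows.append({"codon": j + 1, "class": "no signal", "p": 1.0,
                         "nd": nd, "sd": sd})
            continue
        k = int(round(nd))
        test = stats.binomtest(k, n_changes, p_nonsyn, alternative="two-sided")
        if test.pvalue < alpha and nd / max(n_sites, 1e-9) > sd / max(s_sites, 1e-9):
            cls = "w>1"
        elif test.pvalue < alpha:
            cls = "w<1"
        elif sd > 0 and nd == 0:
            cls = "w<1"
        else:
            cls = "w~1"
        rows.append({"codon": j + 1, "class": cls, "p": float(test.pvalue),
                     "nd": nd, "sd": sd})
    return pd.DataFrame(rows)
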