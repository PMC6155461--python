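"""Population-genetic statistics on genotype and allele-count tables.

Implements observed/expected heterozygosity (Nei's unbiased He), the exact
test of Hardy–Weinberg proportions (complete enumeration for small genotype
table spaces, Markov-chain Monte Carlo otherwise), Weir–Cockerham theta
(FST) with genotype-level permutation tests, and allelic-representation
summaries across geographic strata (base strata ATL, ML, NIRL, SIRL plus
the derived unions IRL = NIRL+SIRL and EST = ML+NIRL+SIRL).

The study's published allele-count table ships as a packaged fixture
(``data/table2_counts.tsv``) and drives every count-based statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger("mhcamplicon")

BASE_STRATA = ["ATL", "ML", "NIRL", "SIRL"]
DERIVED_STRATA = {"IRL": ["NIRL", "SIRL"], "EST": ["ML", "NIRL", "SIRL"]}


@dataclass
class StratumScheme:
    base: list[str] = field(default_factory=lambda: list(BASE_STRATA))
    derived: dict[str, list[str]] = field(default_factory=lambda: dict(DERIVED_STRATA))

    def expand(self, table: pd.DataFrame) -> pd.DataFrame:
        """Add derived-stratum columns as exact elementwise unions."""
        out = table.copy()
        for name, parts in self.derived.items():
            out[name] = sum(out[p] for p in parts)
        return out


def load_allele_counts(path=None) -> pd.DataFrame:
    """Load an allele-count table (locus, allele, one column per stratum)."""
    if path is None:
        path = resources.files("mhcamplicon") / "data" / "table2_counts.tsv"
    with open(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


# ---------------------------------------------------------------------------
# Allele frequencies from genotypes
# ---------------------------------------------------------------------------

def allele_freq_table(genotypes: pd.DataFrame,
                      scheme: StratumScheme | None = None) -> pd.DataFrame:
    """Counts of allele copies per stratum per locus from a genotype table.

    ``genotypes`` columns: sample, stratum, locus, allele1, allele2.
    Individuals missing a locus are dropped for that locus only. Copies per
    stratum = 2 x individuals genotyped there; derived strata are sums.
    """
    scheme = scheme or StratumScheme()
    rows = []
    for locus, sub in genotypes.groupby("locus"):
        missing = sub[sub[["allele1", "allele2"]].isna().any(axis=1)]
        if len(missing):
            log.info("locus %s: dropped %d individuals with missing genotype",
                     locus, len(missing))
            sub = sub.drop(missing.index)
        alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
        for allele in alleles:
            row = {"locus": locus, "allele": allele}
            for stratum in scheme.base:
                s = sub[sub["stratum"] == stratum]
                row[stratum] = int((s["allele1"] == allele).sum()
                                   + (s["allele2"] == allele).sum())
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = scheme.expand(table)
    return table


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class HetResult:
    n: int                         # gene copies (2n)
    ho: float | None               # observed het (needs genotypes)
    he: float                      # Nei's unbiased expected het
    p_value: float | None = None
    sd: float | None = None


def expected_het(counts) -> float:
    """Nei's unbiased expected heterozygosity [2n/(2n-1)](1 - sum p_i^2)."""
    counts = np.asarray(list(counts), dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if total < 2:
        raise ValueError("need >= 2 allele copies")
    if len(counts) < 2:
        return 0.0
    p = counts / total
    return float(total / (total - 1) * (1.0 - (p ** 2).sum()))


def heterozygosity(counts, genotypes: pd.DataFrame | None = None,
                   hwe: bool = False, seed: int | None = None) -> HetResult:
    """He from allele counts; Ho (and optionally an HWE exact p) when
    individual genotypes are available."""
    counts = np.asarray(list(counts), dtype=float)
    he = expected_het(counts)
    ho = None
    p = sd = None
    if genotypes is not None and len(genotypes):
        het = (genotypes["allele1"] != genotypes["allele2"]).sum()
        ho = float(het / len(genotypes))
        if hwe:
            table = genotype_count_table(genotypes)
            p, sd = hwe_exact(table, seed=seed, return_sd=True)
    return HetResult(n=int(counts.sum()), ho=ho, he=he, p_value=p, sd=sd)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def genotype_count_table(genotypes: pd.DataFrame) -> dict[tuple[int, int], int]:
    alleles = sorted(set(genotypes["allele1"]) | set(genotypes["allele2"]))
    index = {a: i for i, a in enumerate(alleles)}
    table: dict[tuple[int, int], int] = {}
    for _, row in genotypes.iterrows():
        i, j = sorted((index[row["allele1"]], index[row["allele2"]]))
        table[(i, j)] = table.get((i, j), 0) + 1
    return table


def _margins(table: dict[tuple[int, int], int]) -> np.ndarray:
    k = max(max(p) for p in table) + 1
    m = np.zeros(k, dtype=int)
    for (i, j), n in table.items():
        m[i] += n
        m[j] += n
    return m


def _log_prob_rel(table: dict[tuple[int, int], int]) -> float:
    """Log of the conditional table probability up to a margins-only constant."""
    h = sum(n for (i, j), n in table.items() if i != j)
    return h * math.log(2.0) - sum(math.lgamma(n + 1) for n in table.values())


def _enumerate_tables(margins: np.ndarray, cap: int):
    """Yield all genotype tables with the given allele-count margins.

    Returns None if more than ``cap`` tables exist (caller falls back to
    MCMC). Tables are dicts {(i, j): count} with i <= j.
    """
    k = len(margins)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    out: list[dict] = []

    def rec(idx: int, remaining: np.ndarray, current: dict):
        if len(out) > cap:
            raise OverflowError
        if idx == len(pairs):
            if not remaining.any():
                out.append(dict(current))
            return
        i, j = pairs[idx]
        later = [p for p in pairs[idx:] if i in p or j in p]
        if i == j:
            hi = remaining[i] // 2
            # if this is the last pair touching allele i, it must absorb it
            for n in range(hi + 1):
                current[(i, i)] = n
                remaining[i] -= 2 * n
                if remaining[i] >= 0 and _feasible(i, pairs, idx + 1, remaining):
                    rec(idx + 1, remaining, current)
                remaining[i] += 2 * n
            del current[(i, i)]
        else:
            hi = min(remaining[i], remaining[j])
            for n in range(hi + 1):
                current[(i, j)] = n
                remaining[i] -= n
                remaining[j] -= n
                if _feasible(i, pairs, idx + 1, remaining) and \
                   _feasible(j, pairs, idx + 1, remaining):
                    rec(idx + 1, remaining, current)
                remaining[i] += n
                remaining[j] += n
            del current[(i, j)]

    def _feasible(a: int, all_pairs, next_idx: int, remaining) -> bool:
        if remaining[a] == 0:
            return True
        rest = [p for p in all_pairs[next_idx:] if a in p]
        if not rest:
            return False
        if all(p == (a, a) for p in rest) and remaining[a] % 2:
            return False
        return True

    try:
        rec(0, margins.copy(), {})
    except OverflowError:
        return None
    return out


def hwe_exact(table: dict[tuple[int, int], int], n_steps: int = 10_000,
              burn_in: int = 1_000, seed: int | None = None,
              enumeration_cap: int = 100_000, method: str = "auto",
              return_sd: bool = False):
    """Exact test of Hardy–Weinberg proportions.

    Complete enumeration of all genotype tables conditional on the allele
    counts when the state space is small; otherwise a Markov-chain Monte
    Carlo estimate using an individual re-pairing proposal (two random
    individuals exchange gene copies; Metropolis acceptance on the
    conditional table probability). p is the probability mass of tables no
    more probable than the observed one. Monomorphic data give p = 1.
    """
    table = {tuple(sorted(p)): n for p, n in table.items() if n > 0}
    if not table:
        raise ValueError("empty genotype table")
    margins = _margins(table)
    if (margins > 0).sum() < 2:
        return (1.0, 0.0) if return_sd else 1.0
    if sum(table.values()) < 2:
        raise ValueError("need >= 2 individuals")

    obs_logp = _log_prob_rel(table)
    tables = None if method == "mcmc" else _enumerate_tables(margins, enumeration_cap)
    if tables is not None and method != "mcmc":
        logps = np.array([_log_prob_rel(t) for t in tables])
        weights = np.exp(logps - logps.max())
        weights /= weights.sum()
        p = float(weights[logps <= obs_logp + 1e-9].sum())
        return (p, 0.0) if return_sd else p

    # --- MCMC fallback.  Conditional on the allele counts, every ordered
    # arrangement of the 2n gene copies into the n individuals' two slots is
    # equally likely (a table's probability n! 2^H / ((2n)!/prod m_i!) /
    # prod n_ij! is exactly its arrangement multiplicity).  A chain that
    # swaps one random gene copy between two random individuals is therefore
    # symmetric with a *uniform* target: every proposal is accepted, and the
    # table statistic is tallied along the way.
    rng = np.random.default_rng(seed)
    genotype_list: list[tuple[int, int]] = []
    for pair, n in table.items():
        genotype_list.extend([pair] * n)
    genotypes = np.array(genotype_list)       # (n, 2), slot-ordered
    counts = dict(table)
    cur_logp = obs_logp
    n_ind = len(genotypes)
    hits = 0
    pair_idx = rng.integers(0, n_ind, size=2 * (burn_in + n_steps))
    slot_idx = rng.integers(0, 2, size=2 * (burn_in + n_steps))
    for step in range(burn_in + n_steps):
        i1, i2 = pair_idx[2 * step], pair_idx[2 * step + 1]
        if i1 != i2:
            s1, s2 = slot_idx[2 * step], slot_idx[2 * step + 1]
            g1 = tuple(sorted(genotypes[i1]))
            g2 = tuple(sorted(genotypes[i2]))
            genotypes[i1, s1], genotypes[i2, s2] = genotypes[i2, s2], genotypes[i1, s1]
            h1 = tuple(sorted(genotypes[i1]))
            h2 = tuple(sorted(genotypes[i2]))
            if (g1, g2) != (h1, h2):
                delta = 0.0
                trial: dict = {}
                for g, sign in ((g1, -1), (g2, -1), (h1, +1), (h2, +1)):
                    n_old = counts.get(g, 0) + trial.get(g, 0)
                    trial[g] = trial.get(g, 0) + sign
                    delta += math.lgamma(n_old + 1) - math.lgamma(n_old + sign + 1)
                    if g[0] != g[1]:
                        delta += sign * math.log(2.0)
                for g, dn in trial.items():
                    counts[g] = counts.get(g, 0) + dn
                    if counts[g] == 0:
                        del counts[g]
                cur_logp += delta
        if step >= burn_in and cur_logp <= obs_logp + 1e-9:
            hits += 1
    p = hits / n_steps
    sd = math.sqrt(max(p * (1 - p), 1e-12) / n_steps)
    return (p, sd) if return_sd else p


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    per_locus: dict[str, float]
    theta: float                    # multi-locus, ratio-of-sums
    p_value: float | None
    n_permutations: int


def _wc_components(strat_idx: np.ndarray, a1: np.ndarray, a2: np.ndarray,
                   n_strata: int, n_alleles: int):
    """Summed Weir–Cockerham variance components (a, a+b+c) for one locus."""
    sizes = np.bincount(strat_idx, minlength=n_strata).astype(float)
    present = sizes > 0
    r = int(present.sum())
    if r < 2:
        return 0.0, 0.0
    sizes = sizes[present]
    remap = -np.ones(n_strata, dtype=int)
    remap[present] = np.arange(r)
    si = remap[strat_idx]

    n_bar = sizes.mean()
    n_total = sizes.sum()
    n_c = (n_total - (sizes ** 2).sum() / n_total) / (r - 1)
    if n_bar <= 1 or n_c <= 0:
        return 0.0, 0.0

    counts = np.zeros((r, n_alleles))
    np.add.at(counts, (si, a1), 1.0)
    np.add.at(counts, (si, a2), 1.0)
    freqs = counts / (2.0 * sizes[:, None])

    het = a1 != a2
    het_counts = np.zeros((r, n_alleles))
    np.add.at(het_counts, (si[het], a1[het]), 1.0)
    np.add.at(het_counts, (si[het], a2[het]), 1.0)
    h = het_counts / sizes[:, None]

    a_sum = abc_sum = 0.0
    for al in range(n_alleles):
        p = freqs[:, al]
        p_bar = float((sizes * p).sum() / n_total)
        if p_bar <= 0 or p_bar >= 1:
            continue
        s2 = float((sizes * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar))
        h_bar = float((sizes * h[:, al]).sum() / n_total)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2.0
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def fst_wc(genotypes: pd.DataFrame, strata: list[str] | None = None,
           n_perm: int = 10_100, seed: int | None = None) -> FstResult:
    """Weir–Cockerham theta between strata with a genotype-permutation test.

    Per-locus theta from variance components; multi-locus theta is the
    ratio of summed components across loci. The permutation test resamples
    individuals (genotype pairs, jointly across loci) between strata; p is
    the fraction of permuted theta >= observed. Loci monomorphic across the
    compared strata contribute nothing and are logged.
    """
    if strata is not None:
        genotypes = genotypes[genotypes["stratum"].isin(strata)]
    strata = sorted(set(genotypes["stratum"])) if strata is None else list(strata)
    if len(strata) < 2:
        raise ValueError("need >= 2 strata")
    samples = sorted(set(genotypes["sample"]))
    sample_idx = {s: i for i, s in enumerate(samples)}
    stratum_of = np.zeros(len(samples), dtype=int)
    for _, row in genotypes.drop_duplicates("sample").iterrows():
        stratum_of[sample_idx[row["sample"]]] = strata.index(row["stratum"])
    for s in strata:
        if (stratum_of == strata.index(s)).sum() < 2:
            raise ValueError(f"stratum {s} has < 2 genotyped individuals")

    loci = {}
    for locus, sub in genotypes.groupby("locus"):
        alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
        amap = {a: i for i, a in enumerate(alleles)}
        loci[locus] = (
            np.array([sample_idx[s] for s in sub["sample"]]),
            np.array([amap[a] for a in sub["allele1"]]),
            np.array([amap[a] for a in sub["allele2"]]),
            len(alleles),
        )

    def theta_all(assignment: np.ndarray):
        per_locus = {}
        tot_a = tot_abc = 0.0
        for locus, (rows, a1, a2, k) in loci.items():
            a_sum, abc_sum = _wc_components(assignment[rows], a1, a2,
                                            len(strata), k)
            if abc_sum == 0.0:
                per_locus[locus] = float("nan")
                continue
            per_locus[locus] = a_sum / abc_sum
            tot_a += a_sum
            tot_abc += abc_sum
        theta = tot_a / tot_abc if tot_abc else float("nan")
        return per_locus, theta

    per_locus, theta = theta_all(stratum_of)
    for locus, th in per_locus.items():
        if math.isnan(th):
            log.info("locus %s monomorphic across compared strata; excluded", locus)

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        labels = stratum_of.copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            _, th = theta_all(labels)
            if not math.isnan(th) and th >= theta - 1e-12:
                hits += 1
        p = hits / n_perm
    return FstResult(per_locus=per_locus, theta=float(theta), p_value=p,
                     n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Allelic representation
# ---------------------------------------------------------------------------

def allelic_representation(table: pd.DataFrame,
                           strata: list[str] | None = None) -> dict[str, int]:
    """Percent of the distinct-allele catalogue present per stratum,
    rounded to whole percent (half away from zero)."""
    if not len(table):
        raise ValueError("empty catalogue")
    strata = strata or [c for c in table.columns if c not in ("locus", "allele")]
    total = len(table)
    out = {}
    for stratum in strata:
        present = int((table[stratum] > 0).sum())
        out[stratum] = int(math.floor(100.0 * present / total + 0.5))
    return out
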