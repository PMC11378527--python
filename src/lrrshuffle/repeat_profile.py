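"""Repeat-unit matrices, consensus profiles, and a per-site
diversifying-selection screen.

The repeat units of one gene (or a pool of genes) are equal-length 23-mers
already aligned by position, so the "alignment" is just a matrix. Column
profiles give the consensus and information content used for sequence
logos. The selection screen asks which of the 23 codon sites show excess
nonsynonymous diversity across repeat copies: per-codon synonymous and
nonsynonymous sites and pathway-averaged differences are counted in the
Nei–Gojobori (1986) style, each site's dN is compared against a pooled
synonymous baseline, and significance comes from a permutation null that
shuffles each unit's codons across sites (exchangeable-sites null), with
Benjamini–Hochberg control across the 23 sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product

import numpy as np
from scipy.stats import false_discovery_control

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "TCAG"
_CODON_AA = {}
for _b1, _b2, _b3 in product(_BASES, repeat=3):
    _c = _b1 + _b2 + _b3
    from Bio.Seq import Seq as _Seq
    _CODON_AA[_c] = str(_Seq(_c).translate())
SENSE_CODONS = tuple(sorted(c for c, a in _CODON_AA.items() if a != "*"))
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


class EmptyFamilyError(ValueError):
    pass


@dataclass
class RepeatFamily:
    """Equal-length repeat-unit matrix, rows in translation order."""

    unit_length: int
    units: list[str]                      # N residue strings
    codon_units: list[list[str]] | None   # N x unit_length codon strings
    provenance: list[str]                 # source label per row
    n_rejected: int = 0

    @property
    def n_units(self) -> int:
        return len(self.units)


def build_family(peptides, codons=None, provenance=None, unit_length: int = 23
                 ) -> RepeatFamily:
    """Assemble a repeat family from 23-mer peptides (and optional codons).

    Rows of the wrong length are rejected and counted; duplicates are kept
    (each repeat copy is an observation). When codons are given they must
    translate to the corresponding peptide row.
    """
    peptides = list(peptides)
    if codons is not None:
        codons = [list(c) for c in codons]
        if len(codons) != len(peptides):
            raise ValueError("codons and peptides differ in row count")
    if provenance is None:
        provenance = [f"unit{i}" for i in range(len(peptides))]
    units, codon_units, prov = [], [], []
    n_rejected = 0
    for i, pep in enumerate(peptides):
        if len(pep) != unit_length:
            n_rejected += 1
            continue
        if codons is not None:
            row = codons[i]
            if len(row) != unit_length:
                n_rejected += 1
                continue
            translated = "".join(_CODON_AA.get(c.upper(), "X") for c in row)
            if translated != pep:
                raise ValueError(
                    f"codon row {i} translates to {translated}, not {pep}"
                )
            codon_units.append([c.upper() for c in row])
        units.append(pep)
        prov.append(provenance[i])
    if not units:
        raise EmptyFamilyError("empty family: no valid repeat units")
    return RepeatFamily(unit_length=unit_length, units=units,
                        codon_units=codon_units if codons is not None else None,
                        provenance=prov, n_rejected=n_rejected)


# ---------------------------------------------------------------------------
# position profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionProfile:
    counts: np.ndarray         # unit_length x 21 (20 aa + X)
    frequencies: np.ndarray    # pseudocount-smoothed, canonical residues
    information: np.ndarray    # bits per position
    consensus: str
    ties: tuple[int, ...]      # 0-based positions where argmax was tied

    @property
    def alphabet(self) -> str:
        return AMINO_ACIDS + "X"


def position_profile(family: RepeatFamily, pseudocount: float = 0.0
                     ) -> PositionProfile:
    """Per-column residue counts, frequencies and information content.

    Information content is ``log2(20) + sum_a p_a log2 p_a`` over the 20
    canonical residues (X is counted but carries no information), with
    frequencies smoothed by ``pseudocount`` per residue. Consensus is the
    argmax count, ties broken alphabetically and recorded.
    """
    L = family.unit_length
    counts = np.zeros((L, 21), dtype=float)
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for unit in family.units:
        for j, res in enumerate(unit):
            counts[j, index.get(res, 20)] += 1.0
    canon = counts[:, :20] + pseudocount
    totals = canon.sum(axis=1, keepdims=True)
    freqs = np.divide(canon, totals, out=np.zeros_like(canon),
                      where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = np.clip(np.log2(20.0) + plogp.sum(axis=1), 0.0, np.log2(20.0))
    consensus, ties = [], []
    for j in range(L):
        col = counts[j, :20]
        best = col.max()
        winners = [AMINO_ACIDS[k] for k in range(20) if col[k] == best]
        consensus.append(winners[0] if best > 0 else "X")
        if len(winners) > 1:
            ties.append(j)
    return PositionProfile(counts=counts, frequencies=freqs,
                           information=info, consensus="".join(consensus),
                           ties=tuple(ties))


# ---------------------------------------------------------------------------
# NG86-style codon counting tables
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts; mutations to stops excluded."""
    syn = 0.0
    nonsyn = 0.0
    aa = _CODON_AA[codon]
    for pos in range(3):
        s = n = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            alt_aa = _CODON_AA[alt]
            if alt_aa == "*":
                continue
            if alt_aa == aa:
                s += 1
            else:
                n += 1
        total = s + n
        if total:
            syn += s / total
            nonsyn += n / total
        else:
            nonsyn += 1.0
    return syn, nonsyn


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All orderings of the differing positions are enumerated with equal
    weight; pathways passing through a stop codon are discarded unless
    every pathway does.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_AA[nxt] == "*":
                through_stop = True
            if _CODON_AA[nxt] == _CODON_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((through_stop, syn, nonsyn))
    valid = [p for p in paths if not p[0]] or paths
    syn = sum(p[1] for p in valid) / len(valid)
    nonsyn = sum(p[2] for p in valid) / len(valid)
    return syn, nonsyn


@lru_cache(maxsize=1)
def _tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    k = len(SENSE_CODONS)
    syn_sites = np.zeros(k)
    nonsyn_sites = np.zeros(k)
    for i, c in enumerate(SENSE_CODONS):
        syn_sites[i], nonsyn_sites[i] = _codon_sites(c)
    sdiff = np.zeros((k, k))
    ndiff = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s, n = _pair_differences(SENSE_CODONS[i], SENSE_CODONS[j])
            sdiff[i, j] = sdiff[j, i] = s
            ndiff[i, j] = ndiff[j, i] = n
    return syn_sites, nonsyn_sites, sdiff, ndiff


def pair_dn_ds_counts(codon1: str, codon2: str
                      ) -> tuple[float, float, float, float]:
    """(syn_diffs, nonsyn_diffs, syn_sites, nonsyn_sites) for one codon pair.

    Site counts are the pair average, differences are pathway-averaged.
    """
    s, n = _pair_differences(codon1.upper(), codon2.upper())
    s1, n1 = _codon_sites(codon1.upper())
    s2, n2 = _codon_sites(codon2.upper())
    return s, n, (s1 + s2) / 2, (n1 + n2) / 2


# ---------------------------------------------------------------------------
# selection screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSelectionResult:
    site: int           # 1-based within the repeat unit
    dn: float
    omega_hat: float
    p_perm: float
    p_adjusted: float
    flagged: bool


@dataclass(frozen=True)
class SelectionScreen:
    results: tuple[SiteSelectionResult, ...]
    pooled_ds: float
    alpha: float
    n_perm: int
    seed: int
    site_numbering: str = "1-based within the 23-residue repeat unit"
    note: str | None = None

    @property
    def flagged_sites(self) -> tuple[int, ...]:
        return tuple(r.site for r in self.results if r.flagged)


def _codon_index_matrix(family: RepeatFamily) -> np.ndarray:
    if family.codon_units is None:
        raise ValueError("selection screen needs the codon matrix")
    try:
        return np.array([[_CODON_INDEX[c] for c in row]
                         for row in family.codon_units], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-sense codon in family: {exc}") from exc


def _column_dn(counts: np.ndarray, n_units: int) -> np.ndarray:
    """Per-column dN from a (sites x 61) codon count matrix."""
    _, nonsyn_sites, _, ndiff = _tables()
    num = 0.5 * np.einsum("js,st,jt->j", counts, ndiff, counts)
    denom = (n_units - 1) / 2.0 * (counts @ nonsyn_sites)
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


def _counts(codidx: np.ndarray) -> np.ndarray:
    n, L = codidx.shape
    k = len(SENSE_CODONS)
    flat = codidx + k * np.broadcast_to(np.arange(L), (n, L))
    return np.bincount(flat.ravel(), minlength=L * k).reshape(L, k).astype(float)


def site_selection_screen(family: RepeatFamily, alpha: float = 0.05,
                          n_perm: int = 999, seed: int = 0
                          ) -> SelectionScreen:
    """Screen each repeat site for diversifying selection.

    Per site, nonsynonymous differences over all unit pairs are divided by
    pair-averaged nonsynonymous sites to give dN; a pooled dS over all
    sites jointly is the synonymous baseline, and ``omega_hat = dN / dS``
    (infinite, with a note, when no synonymous signal exists).

    The permutation null treats sites as exchangeable at the level of
    *deviations*: each unit's codons are classified against the per-site
    consensus codon as consensus / synonymous variant / nonsynonymous
    variant, and each replicate permutes every unit's deviation labels
    across the 23 sites, re-expressing a moved deviation relative to the
    destination site's consensus codon (a random member of its synonymous
    class, or a random codon of a different amino acid). This preserves
    each unit's mutation load — and hence the pairwise clustering a single
    mutated copy induces — while destroying site assignment. Raw codons
    cannot be permuted directly because every site has its own consensus
    codon. ``p = (1 + #{null dN >= dN}) / (n_perm + 1)`` per site, adjusted
    by Benjamini–Hochberg; a site is flagged iff its adjusted p <= alpha
    and ``omega_hat > 1``.
    """
    if n_perm < 199:
        raise ValueError("n_perm must be >= 199")
    if family.n_units < 4:
        raise ValueError("need at least 4 repeat units")
    L = family.unit_length
    codidx = _codon_index_matrix(family)
    n_units = family.n_units
    if len({tuple(r) for r in family.codon_units}) < 2:
        results = tuple(SiteSelectionResult(site=j + 1, dn=0.0, omega_hat=0.0,
                                            p_perm=1.0, p_adjusted=1.0,
                                            flagged=False)
                        for j in range(L))
        return SelectionScreen(results=results, pooled_ds=0.0, alpha=alpha,
                               n_perm=n_perm, seed=seed,
                               note="fewer than 2 distinct units; screening skipped")

    syn_sites, _, sdiff, _ = _tables()
    counts = _counts(codidx)
    dn_obs = _column_dn(counts, n_units)
    syn_num = 0.5 * np.einsum("js,st,jt->j", counts, sdiff, counts).sum()
    syn_den = ((n_units - 1) / 2.0 * (counts @ syn_sites)).sum()
    pooled_ds = syn_num / syn_den if syn_den > 0 else 0.0

    note = None
    if pooled_ds > 0:
        omega = dn_obs / pooled_ds
    else:
        omega = np.where(dn_obs > 0, np.inf, 0.0)
        note = "no synonymous signal; omega set to infinity where dN > 0"

    # canonical row order makes p-values independent of input row order
    codidx = codidx[np.lexsort(codidx.T[::-1])]
    rng = np.random.default_rng(seed)

    aa_idx = np.array([AMINO_ACIDS.index(_CODON_AA[c]) for c in SENSE_CODONS])
    base = np.array([np.bincount(codidx[:, j], minlength=len(SENSE_CODONS))
                     .argmax() for j in range(L)])
    # deviation class of each cell: 0 consensus, 1 synonymous, 2 nonsynonymous
    dev = np.where(codidx == base[None, :], 0,
                   np.where(aa_idx[codidx] == aa_idx[base][None, :], 1, 2))
    syn_choices = [[i for i in range(len(SENSE_CODONS))
                    if aa_idx[i] == aa_idx[b] and i != b] for b in base]
    non_choices = [[i for i in range(len(SENSE_CODONS))
                    if aa_idx[i] != aa_idx[b]] for b in base]
    max_syn = max(1, max(len(s) for s in syn_choices))
    max_non = max(len(s) for s in non_choices)
    syn_tab = np.array([s + [b] * (max_syn - len(s))
                        for s, b in zip(syn_choices, base)])
    non_tab = np.array([s + [s[0]] * (max_non - len(s))
                        for s in non_choices])
    syn_len = np.array([max(len(s), 1) for s in syn_choices])
    non_len = np.array([len(s) for s in non_choices])

    ge = np.zeros(L, dtype=np.int64)
    cols = np.arange(L)
    for _ in range(n_perm):
        perms = rng.permuted(np.broadcast_to(cols, (n_units, L)), axis=1)
        dev_p = np.take_along_axis(dev, perms, axis=1)
        u = rng.random((n_units, L))
        syn_pick = syn_tab[cols, np.minimum((u * syn_len).astype(int),
                                            syn_len - 1)]
        non_pick = non_tab[cols, np.minimum((u * non_len).astype(int),
                                            non_len - 1)]
        null = np.where(dev_p == 0, base[None, :],
                        np.where(dev_p == 1, syn_pick, non_pick))
        dn_null = _column_dn(_counts(null), n_units)
        ge += dn_null >= dn_obs - 1e-12
    p_perm = (1.0 + ge) / (n_perm + 1.0)
    p_adj = false_discovery_control(p_perm, method="bh")
    results = tuple(
        SiteSelectionResult(site=j + 1, dn=float(dn_obs[j]),
                            omega_hat=float(omega[j]),
                            p_perm=float(p_perm[j]),
                            p_adjusted=float(p_adj[j]),
                            flagged=bool(p_adj[j] <= alpha and omega[j] > 1.0))
        for j in range(L))
    return SelectionScreen(results=results, pooled_ds=float(pooled_ds),
                           alpha=alpha, n_perm=n_perm, seed=seed, note=note)
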