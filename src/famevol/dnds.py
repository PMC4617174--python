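"""Nei-Gojobori (1986) synonymous/nonsynonymous divergence with JC correction.

Implements the classic counting estimator used to date homoeolog and
ortholog divergence on a synonymous clock: per-codon synonymous site
fractions (the proportion of the three possible changes at each position
that leave the encoded amino acid unchanged), averaged over both sequences;
observed differences classified by averaging over all minimal substitution
paths between differing codons; and Jukes-Cantor multiple-hit correction
Ks = -3/4 ln(1 - 4 ps / 3) (Ka analogous).

Conventions for stop codons: mutations *to* a stop codon count as
nonsynonymous in site counting (so every sense codon contributes exactly
three sites and S + N = 3 x codons); substitution paths passing *through* a
stop codon are excluded from path averaging; alignment columns containing a
terminal stop codon are dropped, and internal stops are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

__all__ = [
    "KsEstimate",
    "KsUndefinedError",
    "SequenceInputError",
    "codon_sites",
    "codon_differences",
    "ng86_ks",
    "jukes_cantor",
    "divergence_time",
    "DEFAULT_SYNONYMOUS_RATE",
]

#: Synonymous substitution clock (substitutions/site/year) conventional for
#: Brassicaceae divergence dating; Ks ~ 0.435 then corresponds to ~14.5 MY.
DEFAULT_SYNONYMOUS_RATE = 1.5e-8

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"


class SequenceInputError(ValueError):
    """Sequences not comparable: length mismatch, bad symbol, internal stop."""


class KsUndefinedError(ValueError):
    """Observed proportion of differences >= 3/4: JC correction undefined."""


@dataclass(frozen=True)
class KsEstimate:
    """Site/difference counts and corrected rates for one sequence pair."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ks: float
    ka: float

    @property
    def codons(self) -> float:
        return (self.syn_sites + self.nonsyn_sites) / 3.0


def _aa(codon: str) -> str:
    return _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes (number of synonymous single-nucleotide
    changes)/3 synonymous sites; changes producing a stop codon count as
    nonsynonymous.  The two counts always sum to 3.
    """
    if codon in _STOPS:
        raise SequenceInputError(f"stop codon {codon} has no site counts")
    aa0 = _aa(codon)
    syn = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == aa0:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at k positions are connected by k! single-step paths;
    each step is classified synonymous/nonsynonymous and counts are averaged
    over all paths avoiding stop codons (over all paths if every path is
    blocked, which cannot arise for k <= 1).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    path_counts = []
    blocked_counts = []
    for order in permutations(diff_pos):
        syn = nonsyn = 0.0
        current = codon_a
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            step_syn = (
                current not in _STOPS
                and nxt not in _STOPS
                and _aa(current) == _aa(nxt)
            )
            if step_syn:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        (blocked_counts if blocked else path_counts).append((syn, nonsyn))
    pool = path_counts or blocked_counts
    syn = sum(c[0] for c in pool) / len(pool)
    nonsyn = sum(c[1] for c in pool) / len(pool)
    return syn, nonsyn


def _codons(seq: str, name: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise SequenceInputError(f"{name}: length {len(seq)} not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for idx, codon in enumerate(codons):
        if any(nt not in _NUCS for nt in codon):
            raise SequenceInputError(f"{name}: non-ACGT symbol in codon {idx + 1}")
        if codon in _STOPS and idx < len(codons) - 1:
            raise SequenceInputError(f"{name}: internal stop codon at codon {idx + 1}")
    return codons


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differences."""
    if p < 0:
        raise ValueError("proportion of differences must be nonnegative")
    if p >= 0.75:
        raise KsUndefinedError(
            f"proportion of differences {p:.4f} >= 3/4; correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_ks(cds_a: str, cds_b: str) -> KsEstimate:
    """NG86 Ka/Ks for a gap-free pair of aligned coding sequences."""
    codons_a = _codons(str(cds_a), "cds_a")
    codons_b = _codons(str(cds_b), "cds_b")
    if len(codons_a) != len(codons_b):
        raise SequenceInputError(
            f"length mismatch: {3 * len(codons_a)} vs {3 * len(codons_b)} nt"
        )
    sites_a = sites_b = 0.0
    nsites_a = nsites_b = 0.0
    sd = nd = 0.0
    n_columns = 0
    for ca, cb in zip(codons_a, codons_b):
        if ca in _STOPS or cb in _STOPS:
            # terminal stop column (internal stops already rejected)
            continue
        n_columns += 1
        s_a, n_a = codon_sites(ca)
        s_b, n_b = codon_sites(cb)
        sites_a += s_a
        sites_b += s_b
        nsites_a += n_a
        nsites_b += n_b
        d_s, d_n = codon_differences(ca, cb)
        sd += d_s
        nd += d_n
    if n_columns == 0:
        raise SequenceInputError("no comparable codon columns")
    syn_sites = 0.5 * (sites_a + sites_b)
    nonsyn_sites = 0.5 * (nsites_a + nsites_b)
    ps = sd / syn_sites if syn_sites > 0 else 0.0
    pn = nd / nonsyn_sites if nonsyn_sites > 0 else 0.0
    return KsEstimate(
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        ps=ps,
        pn=pn,
        ks=jukes_cantor(ps),
        ka=jukes_cantor(pn),
    )


def divergence_time(ks: float, rate: float = DEFAULT_SYNONYMOUS_RATE) -> float:
    """Divergence time in million years: T = Ks / (2 * rate).

    Two lineages each accumulate synonymous substitutions at ``rate`` per
    site per year, so pairwise Ks grows at twice that rate.
    """
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return ks / (2.0 * rate) / 1.0e6
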