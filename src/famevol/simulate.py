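"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators for (i) a triplicated genome undergoing subgenome-biased
fractionation, with an optional retention-biased focal family; (ii)
long-format qPCR Ct tables for treated and time-matched control samples
with planted log2 fold-change trajectories and a stable reference gene;
(iii) codon-sequence pairs of calibrated synonymous divergence for
exercising the NG86 estimator; and (iv) presence/absence matrices with
known gain branches for the Dollo footprint.

Default fractionation probabilities (LF 0.30, MF1 0.55, MF2 0.65)
approximate the published genome-wide subgenome retention bias of
*Brassica rapa*.  Ct baselines default to 22 cycles for target genes and
18 for the (more abundant) reference transcript; both are arbitrary but
fixed, and cancel exactly in ddCt analysis.  All generators are driven by
explicit seeds: identical configuration means byte-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .footprint import SpeciesTree
from .retention import SUBGENOMES

__all__ = [
    "SimulationConfig",
    "DEFAULT_LOSS_PROB",
    "gene_ids",
    "ancestral_gene_order",
    "simulate_fractionation",
    "simulate_ct_table",
    "simulate_codon_pair",
    "simulate_presence_matrix",
]

logger = logging.getLogger(__name__)

#: Genome-wide per-subgenome copy-loss probabilities after triplication.
DEFAULT_LOSS_PROB: dict[str, float] = {"LF": 0.30, "MF1": 0.55, "MF2": 0.65}

#: Stress time course in hours (includes the 0 h baseline).
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 1.0, 6.0, 12.0, 24.0, 48.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters shared by the fractionation and qPCR generators."""

    seed: int = 0
    n_genes: int = 1000
    n_chromosomes: int = 5
    loss_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_PROB)
    )
    focal_ids: tuple[str, ...] = ()
    focal_loss_multiplier: float = 1.0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_chromosomes < 1 or self.n_chromosomes > self.n_genes:
            raise ValueError("need 1 <= n_chromosomes <= n_genes")
        if set(self.loss_prob) != set(SUBGENOMES):
            raise ValueError(
                f"loss_prob must have exactly the subgenome keys {SUBGENOMES}"
            )
        for s, p in self.loss_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"loss_prob[{s}]={p} outside [0, 1]")
        if self.focal_loss_multiplier < 0:
            raise ValueError("focal_loss_multiplier must be nonnegative")
        ids = set(gene_ids(self))
        stray = set(self.focal_ids) - ids
        if stray:
            raise ValueError(f"focal_ids not among generated genes: {sorted(stray)}")
        tps = self.timepoints
        if not tps or tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must start at 0 and strictly increase")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gene_ids(config: SimulationConfig) -> list[str]:
    """Ancestral gene identifiers g00001..g<n>, in genome order."""
    width = max(5, len(str(config.n_genes)))
    return [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]


def ancestral_gene_order(config: SimulationConfig) -> pd.DataFrame:
    """Ordered gene list (chrom, position, gene_id) of the ancestral genome.

    Genes are laid out in contiguous, near-equal blocks over
    ``n_chromosomes``; positions are 1-based integer ranks per chromosome.
    """
    ids = gene_ids(config)
    blocks = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    rows = []
    for c, block in enumerate(blocks):
        for pos, idx in enumerate(block, start=1):
            rows.append((f"chr{c + 1}", pos, ids[idx]))
    return pd.DataFrame(rows, columns=["chrom", "position", "gene_id"])


def simulate_fractionation(config: SimulationConfig) -> pd.DataFrame:
    """Triplicate every ancestral gene, then delete copies independently.

    Each gene starts with one copy per subgenome; the copy in subgenome *s*
    is deleted with probability ``loss_prob[s]``, multiplied by
    ``focal_loss_multiplier`` for focal genes (clamped to [0, 1] with a
    logged warning if the product leaves the unit interval).  Returns a
    synteny table (ancestral_id, copy_id, subgenome, chrom, position)
    preserving ancestral gene order within chromosomes.
    """
    order = ancestral_gene_order(config)
    focal = set(config.focal_ids)
    rng = np.random.default_rng(config.seed)
    is_focal = order["gene_id"].isin(focal).to_numpy()
    rows = []
    for s in SUBGENOMES:
        p = np.full(config.n_genes, config.loss_prob[s])
        p[is_focal] *= config.focal_loss_multiplier
        if (p > 1.0).any():
            logger.warning(
                "focal loss probability for subgenome %s clamped to 1", s
            )
            p = np.clip(p, 0.0, 1.0)
        keep = rng.random(config.n_genes) >= p
        kept = order[keep]
        for gid, chrom, pos in zip(kept["gene_id"], kept["chrom"], kept["position"]):
            rows.append((gid, f"{gid}-{s}", s, chrom, pos))
    table = pd.DataFrame(
        rows, columns=["ancestral_id", "copy_id", "subgenome", "chrom", "position"]
    )
    return table.sort_values(
        ["chrom", "position", "subgenome"], kind="mergesort"
    ).reset_index(drop=True)


Profiles = Mapping[str, Mapping[str, Mapping[float, float]]]


def simulate_ct_table(
    config: SimulationConfig,
    profiles: Profiles,
    reference_gene: str = "BcGAPDH",
    baseline_target: float = 22.0,
    baseline_reference: float = 18.0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table with planted log2 fold-change trajectories.

    ``profiles`` maps gene -> treatment -> timepoint -> planted log2 fold
    change of the treated sample relative to the time-matched control.  The
    reference gene must be included with an all-zero (flat) profile.  A Ct
    value is baseline - planted_log2fc + Gaussian noise for treated samples
    and baseline + noise for controls (one more template doubling = one
    cycle earlier), with independent noise per measurement.
    """
    if reference_gene not in profiles:
        raise ValueError(f"reference gene {reference_gene!r} missing from profiles")
    treatments = sorted({t for prof in profiles.values() for t in prof})
    for tr in treatments:
        ref_prof = profiles[reference_gene].get(tr)
        if ref_prof is None or any(ref_prof.get(tp, 0.0) != 0.0 for tp in config.timepoints):
            raise ValueError(
                f"reference gene {reference_gene!r} must have a flat (all-zero) "
                f"profile for treatment {tr!r}"
            )
    for gene, prof in profiles.items():
        for tr in treatments:
            if tr not in prof:
                raise ValueError(f"gene {gene!r} missing treatment {tr!r}")
            missing = [tp for tp in config.timepoints if tp not in prof[tr]]
            if missing:
                raise ValueError(
                    f"gene {gene!r}, treatment {tr!r}: missing timepoint(s) {missing}"
                )
    rng = np.random.default_rng(config.seed)
    rows = []
    for gene in sorted(profiles):
        base = baseline_reference if gene == reference_gene else baseline_target
        for tr in treatments:
            for tp in config.timepoints:
                planted = profiles[gene][tr][tp]
                for rep in range(1, config.n_replicates + 1):
                    for sample_class, shift in (("treated", planted), ("control", 0.0)):
                        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
                        rows.append(
                            (gene, tr, tp, rep, sample_class, base - shift + noise)
                        )
    return pd.DataFrame(
        rows,
        columns=["gene", "treatment", "timepoint_h", "replicate", "sample_class", "ct"],
    )


# Codon families whose third position is fourfold degenerate and whose first
# and second positions admit no synonymous change: every codon contributes
# exactly one synonymous site, so the planted per-site difference rate maps
# one-to-one onto NG86's ps.
_FOURFOLD_PREFIXES = ("GG", "GC", "AC", "GT", "CC")
_NUCS = np.array(list("ACGT"))


def simulate_codon_pair(
    n_codons: int, target_ks: float, seed: int = 0
) -> tuple[str, str]:
    """Ancestral/derived coding pair with calibrated synonymous divergence.

    The ancestral sequence is built from fourfold-degenerate codon families
    (Gly/Ala/Thr/Val/Pro), and the derived copy differs only at synonymous
    third positions: each is substituted with probability
    ps = 3/4 (1 - exp(-4 Ks / 3)) — the Jukes-Cantor inverse — by a uniform
    draw from the three alternative nucleotides.  The encoded protein is
    unchanged and no stop codons can arise.  Pairs whose expected difference
    proportion leaves too little room below the JC singularity at 3/4 for
    the requested length are refused.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if target_ks < 0:
        raise ValueError("target_ks must be nonnegative")
    ps = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    if ps > 0.75 * (1.0 - 3.0 / n_codons):
        raise ValueError(
            f"target_ks={target_ks} too large for n_codons={n_codons}: expected "
            f"difference proportion {ps:.4f} leaves the JC correction undefined"
        )
    rng = np.random.default_rng(seed)
    prefixes = rng.choice(_FOURFOLD_PREFIXES, size=n_codons)
    thirds = rng.choice(_NUCS, size=n_codons)
    mutate = rng.random(n_codons) < ps
    new_thirds = thirds.copy()
    for i in np.flatnonzero(mutate):
        new_thirds[i] = rng.choice([n for n in _NUCS if n != thirds[i]])
    ancestral = "".join(p + t for p, t in zip(prefixes, thirds))
    derived = "".join(p + t for p, t in zip(prefixes, new_thirds))
    return ancestral, derived


def example_profile_panel(
    config: SimulationConfig,
    treatments: Sequence[str] = ("ABA", "cold"),
    reference_gene: str = "BcGAPDH",
) -> Profiles:
    """A 13-gene planted log2 fold-change panel emulating a stress study.

    Three correlated blocks (strongly induced, moderately induced, flat)
    plus one anti-correlated (repressed) gene, under two treatments, with a
    flat reference gene.  Trajectories rise to a peak at 24 h and relax by
    48 h; amplitudes differ between treatments so the two time courses are
    informative but not identical.
    """
    peak_shape = {0.0: 0.0, 1.0: 0.3, 6.0: 0.6, 12.0: 0.8, 24.0: 1.0, 48.0: 0.5}

    def shape(tp: float) -> float:
        if tp in peak_shape:
            return peak_shape[tp]
        return min(tp / 24.0, 1.0)  # generic ramp for non-default grids

    amplitudes = {
        "BcSnRK2.6a": {"ABA": 4.0, "cold": 3.5},
        "BcSnRK2.2": {"ABA": 3.0, "cold": 2.0},
        "BcSnRK2.3": {"ABA": 3.0, "cold": 2.2},
        "BcSnRK2.6b": {"ABA": -2.0, "cold": -2.5},
        "BcSnRK2.1a": {"ABA": 1.5, "cold": 2.0},
        "BcSnRK2.1b": {"ABA": 2.0, "cold": 2.5},
        "BcSnRK2.4a": {"ABA": 1.2, "cold": 2.0},
        "BcSnRK2.4b": {"ABA": 1.5, "cold": 3.0},
        "BcSnRK2.7": {"ABA": 2.0, "cold": -1.5},
        "BcSnRK2.8a": {"ABA": 0.0, "cold": 0.0},
        "BcSnRK2.8b": {"ABA": 2.5, "cold": 3.0},
        "BcSnRK2.5": {"ABA": 0.0, "cold": -1.0},
        "BcSnRK2.10": {"ABA": -1.0, "cold": 1.5},
    }
    panel: dict[str, dict[str, dict[float, float]]] = {}
    for gene, amps in amplitudes.items():
        panel[gene] = {
            tr: {tp: amps.get(tr, 0.0) * shape(tp) for tp in config.timepoints}
            for tr in treatments
        }
    panel[reference_gene] = {
        tr: {tp: 0.0 for tp in config.timepoints} for tr in treatments
    }
    return panel


def simulate_presence_matrix(
    tree: SpeciesTree, gains: Mapping[str, str]
) -> pd.DataFrame:
    """Presence/absence matrix implied by planted gain branches.

    Each member is present (count 1) in exactly the species descending from
    its gain branch and absent elsewhere.  Unknown branch identifiers raise
    ``KeyError``.
    """
    species = sorted(tree.leaf_labels)
    rows = {}
    for member in sorted(gains):
        under = tree.leaves_under(gains[member])
        rows[member] = [1 if s in under else 0 for s in species]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    matrix.index.name = "member"
    return matrix
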