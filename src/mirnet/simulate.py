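"""Synthetic DE tables and target maps with planted structure.

The generator emulates the *inputs* of the enrichment screen, not raw
RNA-seq: a gene universe at transcriptome scale (16,000 genes by default)
with a pathway of 50 genes, of which 17 are planted as genuinely
downregulated; 353 miRNA target sets drawn uniformly from the universe; and
optionally one or more "driver" miRNAs whose target sets are forced to
contain a fixed number of the planted downregulated genes (standing in for
a real repressor of the pathway).

Planted-down genes get log2FC ~ Normal(-effect_mu, noise_sd) and every other
gene Normal(0, noise_sd); raw p-values come from the exact two-sided z-test
of log2FC / noise_sd, so adjusted p-values are reconstructible and the DE
table behaves like the output of a well-calibrated DE fit. Driver planting
swaps planted genes into the target set without changing its size, so
enrichment is never confounded with set size.

Everything is deterministic given the scenario seed; replicate r of an
experiment with ``base_seed`` uses scenario seed ``base_seed + r``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust, mirna_enrichment, rank_mirnas
from .io import DifferentialExpressionTable, GeneSet, TargetMap

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "SyntheticDataset",
    "RecoveryReport",
    "generate",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic dataset. Defaults mirror the scale of a
    human liver transcriptome screen: 16,000 analyzed genes, a 50-gene
    pathway with 17 downregulated members, 353 miRNAs with 10-400 conserved
    targets each, and one planted driver miRNA."""

    n_universe: int = 16_000
    pathway_size: int = 50
    n_down: int = 17
    n_mirnas: int = 353
    target_size_range: tuple[int, int] = (10, 400)
    n_drivers: int = 1
    driver_overlap: int = 8
    effect_mu: float = 1.5   # mean downward log2FC shift of planted genes
    noise_sd: float = 0.3    # log2FC standard deviation, all genes
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.target_size_range
        if not (0 <= self.n_down <= self.pathway_size <= self.n_universe):
            raise ValueError("require n_down <= pathway_size <= n_universe")
        if not (1 <= lo <= hi <= self.n_universe):
            raise ValueError("invalid target_size_range")
        if self.n_drivers < 0 or self.n_mirnas < self.n_drivers:
            raise ValueError("n_drivers must be in [0, n_mirnas]")
        if self.n_drivers > 0 and self.driver_overlap > min(self.n_down, lo):
            raise ValueError(
                f"driver_overlap={self.driver_overlap} cannot exceed "
                f"min(n_down={self.n_down}, smallest target size={lo})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        if "target_size_range" in d:
            d = {**d, "target_size_range": tuple(d["target_size_range"])}
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Generated inputs plus ground truth for recovery scoring."""

    de: DifferentialExpressionTable
    targets: TargetMap
    pathway: GeneSet
    truth_down: frozenset[str]
    truth_drivers: tuple[str, ...]


def _gene_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n - 1)))
    return np.array([f"G{i:0{width}d}" for i in range(n)])


def generate(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate one synthetic dataset; identical output for identical
    (scenario, seed)."""
    s = scenario
    rng = np.random.default_rng(s.seed)
    gene_ids = _gene_ids(s.n_universe)

    pathway_idx = rng.choice(s.n_universe, s.pathway_size, replace=False, shuffle=False)
    planted_idx = pathway_idx[: s.n_down]
    planted_mask = np.zeros(s.n_universe, dtype=bool)
    planted_mask[planted_idx] = True

    log2_fc = rng.normal(0.0, s.noise_sd, s.n_universe)
    log2_fc[planted_idx] = rng.normal(-s.effect_mu, s.noise_sd, s.n_down)
    p_raw = 2.0 * stats.norm.sf(np.abs(log2_fc) / s.noise_sd)
    p_adj = bh_adjust(p_raw)

    de = DifferentialExpressionTable(
        pd.DataFrame(
            {"log2_fc": log2_fc, "p_raw": p_raw, "p_adj": p_adj},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    pathway = GeneSet("SYNTHETIC_PATHWAY", frozenset(gene_ids[pathway_idx]))

    lo, hi = s.target_size_range
    sizes = rng.integers(lo, hi + 1, s.n_mirnas)
    width = max(4, len(str(s.n_mirnas)))
    mirna_ids = [f"MIR{i:0{width}d}" for i in range(s.n_mirnas)]
    planted_set = set(planted_idx.tolist())
    targets: dict[str, frozenset[str]] = {}
    for k in range(s.n_mirnas):
        idx = rng.choice(s.n_universe, int(sizes[k]), replace=False, shuffle=False)
        if k < s.n_drivers:
            idx = _force_overlap(idx, planted_idx, planted_set, s.driver_overlap,
                                 s.n_universe, rng)
        targets[mirna_ids[k]] = frozenset(gene_ids[idx])
    return SyntheticDataset(
        de=de,
        targets=TargetMap(targets, name="synthetic"),
        pathway=pathway,
        truth_down=frozenset(gene_ids[planted_idx]),
        truth_drivers=tuple(mirna_ids[: s.n_drivers]),
    )


def _force_overlap(idx, planted_idx, planted_set, k, n_universe, rng):
    """Adjust a target-set index array to contain exactly k planted genes,
    preserving set size (swap-in / swap-out)."""
    idx = list(idx.tolist())
    members = set(idx)
    current = [i for i in idx if i in planted_set]
    if len(current) > k:
        drop = set(rng.choice(np.array(current), len(current) - k, replace=False).tolist())
        idx = [i for i in idx if i not in drop]
        members -= drop
        fill: list[int] = []
        while len(fill) < len(drop):  # replace with non-planted non-members
            cand = int(rng.integers(0, n_universe))
            if cand not in members and cand not in planted_set:
                fill.append(cand)
                members.add(cand)
        idx.extend(fill)
    elif len(current) < k:
        missing = [i for i in planted_idx.tolist() if i not in members]
        add = rng.choice(np.array(missing), k - len(current), replace=False).tolist()
        # evict random non-planted members to keep the size fixed
        non_planted = np.array([i for i in idx if i not in planted_set])
        evict = set(rng.choice(non_planted, k - len(current), replace=False).tolist())
        idx = [i for i in idx if i not in evict]
        idx.extend(int(a) for a in add)
    return np.array(idx)


@dataclass
class RecoveryReport:
    """Summary of a replicated planted-driver recovery experiment."""

    n_reps: int
    n_failed: int                      # reps with no downregulated gene (D=0)
    driver_top1_rate: float | None     # None when no driver is planted
    driver_in_top10_rate: float | None
    empirical_fdr: float               # mean FDP among calls at p_adjusted <= alpha_call
    alpha_call: float
    driver_ranks: list[int]            # best driver rank per successful rep (1-based)
    fdp_per_rep: list[float]

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "driver_top1_rate": self.driver_top1_rate,
            "driver_in_top10_rate": self.driver_in_top10_rate,
            "empirical_fdr": self.empirical_fdr,
            "alpha_call": self.alpha_call,
            "driver_ranks": self.driver_ranks,
        }


def recovery_experiment(
    scenario: SyntheticScenario,
    n_reps: int,
    base_seed: int = 0,
    alpha_select: float = 0.1,
    alpha_call: float = 0.05,
    collect_null_pvalues: bool = False,
):
    """Replicate generate → select → enrich → rank and score driver recovery.

    Per replicate r the scenario is regenerated with seed ``base_seed + r``.
    Reports the fraction of replicates where the best planted driver ranks
    first (and within the top ten), and the empirical false-discovery
    proportion among miRNAs called at ``p_adjusted <= alpha_call``
    (non-driver calls are false). Replicates where no gene passes the
    downregulation threshold are excluded and counted.

    With ``collect_null_pvalues=True`` also returns the pooled raw p-values
    of all non-driver miRNAs (for calibration checks).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ranks: list[int] = []
    fdps: list[float] = []
    null_pvalues: list[np.ndarray] = []
    n_failed = 0
    for rep in range(n_reps):
        ds = generate(replace(scenario, seed=base_seed + rep))
        try:
            records = mirna_enrichment(
                ds.de, ds.targets, ds.pathway, alpha_select=alpha_select
            )
        except ValueError:
            n_failed += 1
            log.warning("replicate %d: no downregulated gene; excluded", rep)
            continue
        ranked = rank_mirnas(records)
        drivers = set(ds.truth_drivers)
        if drivers:
            best = min(
                i + 1 for i, rec in enumerate(ranked) if rec.mirna_id in drivers
            )
            ranks.append(best)
        calls = [r for r in ranked if r.p_adjusted <= alpha_call]
        if calls:
            false_calls = sum(1 for r in calls if r.mirna_id not in drivers)
            fdps.append(false_calls / len(calls))
        else:
            fdps.append(0.0)
        if collect_null_pvalues:
            null_pvalues.append(
                np.array([r.p_value for r in records if r.mirna_id not in drivers])
            )
    n_ok = n_reps - n_failed
    report = RecoveryReport(
        n_reps=n_reps,
        n_failed=n_failed,
        driver_top1_rate=(
            sum(r == 1 for r in ranks) / n_ok if scenario.n_drivers and n_ok else None
        ),
        driver_in_top10_rate=(
            sum(r <= 10 for r in ranks) / n_ok if scenario.n_drivers and n_ok else None
        ),
        empirical_fdr=float(np.mean(fdps)) if fdps else 0.0,
        alpha_call=alpha_call,
        driver_ranks=ranks,
        fdp_per_rep=fdps,
    )
    if collect_null_pvalues:
        pooled = np.concatenate(null_pvalues) if null_pvalues else np.array([])
        return report, pooled
    return report
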