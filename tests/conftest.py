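"""Shared fixtures: the bundled 10-gene / 3-miRNA toy screen and small
independent oracles used across test modules."""

import itertools
import math
from pathlib import Path

import pandas as pd
import pytest

from mirnet import (
    DifferentialExpressionTable,
    GeneSet,
    TargetMap,
    read_de_table,
    read_gmt,
    read_target_map,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def toy_de() -> DifferentialExpressionTable:
    return read_de_table(DATA / "toy_de.tsv")


@pytest.fixture(scope="session")
def toy_pathway() -> GeneSet:
    return read_gmt(DATA / "toy_pathway.gmt")[0]


@pytest.fixture(scope="session")
def toy_targets() -> TargetMap:
    return read_target_map(DATA / "toy_targets.tsv", min_targets=1)


def hypergeom_tail_by_enumeration(n: int, m: int, d: int, o: int) -> float:
    """Exhaustive oracle: fraction of all C(n, m) target subsets containing
    at least o of the d marked genes. Only feasible for small n."""
    marked = set(range(d))
    total = 0
    hits = 0
    for subset in itertools.combinations(range(n), m):
        total += 1
        if len(marked.intersection(subset)) >= o:
            hits += 1
    return hits / total


def bh_by_hand(p_values):
    """Textbook step-up: p(i) * n / i with a running minimum from the
    largest rank down, capped at 1."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, p_values[i] * n / rank))
        adjusted[i] = running_min
    return adjusted


def pearson_two_pass(x, y) -> float:
    """Naive two-pass Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def naive_seed_sites(seed7: str, utr: str):
    """Brute-force sliding-window seed-site finder over a DNA-alphabet UTR.

    seed7 is the miRNA's 7-nt seed (positions 2-8, RNA). Returns
    (site_type, start, end) tuples, one per 6mer-core occurrence at the
    longest applicable type.
    """
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    to_dna = {"A": "A", "U": "T", "C": "C", "G": "G"}
    core = "".join(to_dna[comp[b]] for b in reversed(seed7[:6]))
    m8 = to_dna[comp[seed7[6]]]
    utr = utr.upper().replace("U", "T")
    out = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        has_m8 = i > 0 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            out.append(("8mer", i - 1, i + 7))
        elif has_m8:
            out.append(("7mer-m8", i - 1, i + 6))
        elif has_a1:
            out.append(("7mer-A1", i, i + 7))
        else:
            out.append(("6mer", i, i + 6))
    return out


def make_de(rows: dict[str, tuple[float, float, float]]) -> DifferentialExpressionTable:
    """Build a DE table from {gene: (log2_fc, p_raw, p_adj)}."""
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["log2_fc", "p_raw", "p_adj"]
    )
    frame.index.name = "gene_id"
    return DifferentialExpressionTable(frame)
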