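"""Locate canonical MIR20B seed-match sites in a synthetic PPARA-like 3'UTR.

The UTR is a random 600-nt sequence (synthetic, not the real PPARA 3'UTR)
with one 8mer and one 7mer-m8 MIR20B site planted at known positions, so
the scanner's site-type classification is visible on realistic input.
Writes results/mir20b_sites.tsv.
"""

from pathlib import Path

import numpy as np

from mirnet import MatureMirna, scan_utr, seed_of
from mirnet.seeds import write_sites

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

mir20b = MatureMirna("MIR20B", "CAAAGUGCUCAUAGUGCAGGUAG")
print(f"MIR20B seed (positions 2-8): {seed_of(mir20b)}")

rng = np.random.default_rng(20)
bases = np.array(list("ACGT"))
utr = list("".join(bases[rng.integers(0, 4, 600)].tolist()))
utr[100:108] = list("GCACTTTA")   # 8mer: m8 match + seed core + A1
utr[300:307] = list("GCACTTTG")   # 7mer-m8: no A1 adenosine
utr = "".join(utr)

sites = scan_utr(mir20b, utr, "PPARA_UTR_SYNTHETIC")
for s in sites:
    print(f"  {s.site_type:8s} at [{s.start}, {s.end}) on {s.utr_id}")
write_sites(sites, OUT / "mir20b_sites.tsv")
print(f"wrote {OUT / 'mir20b_sites.tsv'} ({len(sites)} sites)")
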