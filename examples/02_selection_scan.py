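"""Locate a selective sweep with a windowed, power-transformed FST scan.

Simulates a panel whose two most recent breeding periods carry a fixed
alternative allele over a 40 Mbp region of chromosome 5H, then scans
the genome with 500 kb windows at 250 positions per chromosome.
Raising FST to the 10th power suppresses the genome-wide background so
the swept region stands out; unique-allele counts show the turnover of
common variants between the extreme periods.
"""

import numpy as np

import dartpop as dp
from dartpop.reference import chromosome_lengths_bp

cfg = dp.SimConfig(
    loci_per_chromosome={c: 1000 for c in
                         ("1H", "2H", "3H", "4H", "5H", "6H", "7H")},
    sweep_spec=[("5H", 120e6, 40e6, ("1990-1999", "post-2000"))],
    seed=4)
gm, info, meta, truth = dp.generate_panel(cfg)
gm, info, _ = dp.filter_loci(gm, info)

tracks = dp.selection_scan_report(gm, info, meta, "pre-1945", "post-2000",
                                  chromosome_lengths_bp())
rows = dp.tracks_to_frame(tracks["fst_transformed"])
top = rows.loc[rows["value"].idxmax()]
print(f"top FST^10 window: {top['chromosome']} at "
      f"{top['center_bp'] / 1e6:.1f} Mbp (value {top['value']:.3f})")
print("the planted sweep spans 5H 100-140 Mbp, so the scan localises it.")

per_chrom = rows.groupby("chromosome")["value"].max()
print("\nmax windowed FST^10 per chromosome:")
for c, v in per_chrom.items():
    print(f"  {c}: {v:.4f}")

groups = dp.group_indices(meta, gm)
ua = dp.unique_alleles(gm, info, groups["pre-1945"], groups["post-2000"],
                       threshold=0.25)
tab = ua.set_index("chromosome")
print(f"\ncommon alleles (freq >= 0.25) lost from the oldest period: "
      f"{tab.loc['total', 'n_lost']}, gained in the newest: "
      f"{tab.loc['total', 'n_gained']}")
print(f"on the sweep chromosome 5H alone: lost {tab.loc['5H', 'n_lost']}, "
      f"gained {tab.loc['5H', 'n_gained']} — the fixed sweep alleles "
      f"displace the old variants.")
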