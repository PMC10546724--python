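"""Cis-co-accessibility networks from a planted precision structure.

Draws aggregated accessibility profiles whose true precision matrix has
5-peak blocks, estimates co-accessibility scores with the distance-penalized
graphical lasso, and extracts CCANs by Louvain community detection.
"""

from cistrans.ccan import coaccessibility, extract_ccans
from cistrans.synthetic import CCANBlock, default_config, generate_annotation, generate_coaccessible_counts

cfg = default_config(seed=0)
cfg.ccan_blocks = [CCANBlock(b.peak_indices, partial_corr=0.24) for b in cfg.ccan_blocks]
ann = generate_annotation(cfg)
samples, theta = generate_coaccessible_counts(cfg, n_samples=500)

edges = coaccessibility(samples, ann.peaks, ann.peak_ids)
strong = edges[edges["score"] >= 0.2]
print(f"{len(edges)} peak pairs within 500 kb scored; {len(strong)} with score >= 0.2")

for ccan in extract_ccans(edges):
    print(f"{ccan.id}: {len(ccan.peaks)} peaks, e.g. {ccan.peaks[0]} .. {ccan.peaks[-1]}")
# With well-separated blocks every planted 5-peak block comes back as one
# CCAN and background pairs stay below the 0.2 score threshold.
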