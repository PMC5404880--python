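"""Build a reference-point signal matrix and quantify enhancer bimodality.

Enhancer histone marks (H3K27ac here) flank the bound centre on both sides,
so their metagene profile around site centres is bimodal. The bimodality
index (mean flank signal / mean centre signal) quantifies that shape and
its collapse at Type 1 sites over the withdrawal time course.
"""

from epitype.signal import bimodality_index, metagene_profile, normalize_per_million, signal_matrix
from epitype.simulate import SimulationConfig, simulate_tracks, simulate_truth

cfg = SimulationConfig(seed=7)
truth = simulate_truth(cfg)
tracks = simulate_tracks(truth, cfg, assays=("H3K27ac",))

type1 = truth.sites_of_type("Type1")
print(f"{len(type1)} Type 1 sites; window +/-1500 bp, 50 bp bins")
for tp in cfg.timepoints:
    track = normalize_per_million(tracks[f"H3K27ac:{tp}"])
    matrix = signal_matrix(track, type1, window=1500, bin_size=50)
    index = bimodality_index(metagene_profile(matrix))
    print(f"  H3K27ac {tp:>9}: bimodality index = {index:.2f}")
print("An index > 1 means flanking enrichment (active-enhancer nucleosome")
print("configuration); the monotone decrease after withdrawal shows Type 1")
print("enhancer marks depend on continued factor expression.")
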