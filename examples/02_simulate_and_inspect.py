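"""Generate a small planted-motif dataset and look at what it contains.

Positives carry a noisy copy of the consensus GAGTCA at a random offset in
the left flank; negatives are uniform background.  Both classes force the
central base to 'C', mimicking cytosine-centered methylation windows, so
the center itself carries no class signal.
"""

from mc4pred import SimConfig, simulate

cfg = SimConfig(n_pos=5, n_neg=5, match_prob=0.9, seed=42)
windows, manifest = simulate(cfg)

print(f"{len(windows)} windows of length {cfg.seq_len}, motif {cfg.motif!r}, "
      f"match_prob {cfg.match_prob}\n")
for w, row in zip(windows[:5], manifest):
    s = row["motif_start"]
    marked = (w.sequence[:s] + "[" + w.sequence[s : s + 6] + "]"
              + w.sequence[s + 6 :])
    print(f"{w.id}: {marked}  realized={row['realized_motif']}")
for w in windows[5:]:
    print(f"{w.id}: {w.sequence}")
print("\nBrackets mark the planted (possibly corrupted) motif; every window "
      "has 'C' at position 21.")
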