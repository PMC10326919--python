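"""Generate synthetic replicate spectra and inspect their correlation structure.

Replicate EI spectra of one compound are not independent measurements: the
normalised fragment abundances rise and fall together with the instrument's
effective internal-energy state.  The generator reproduces that structure
through a one-dimensional latent factor.
"""

import numpy as np

import easi

spec = easi.default_spec()
raw = easi.simulate_replicates(spec, n=128, seed=11)
train = easi.nominalize(raw)

panel = easi.select_top_k(train, 20)
matrix = easi.assemble_matrix(train, panel)
consensus = easi.build_consensus(train, panel)

print(f"simulated {len(train)} replicate spectra of '{spec.compound}'")
print(f"panel (20 most abundant channels): {panel.channels}")
print("\nconsensus spectrum (mean % of base peak +/- sd):")
for c, m, s in zip(panel.channels[:8], consensus.mean, consensus.sd):
    print(f"  m/z {c:>3}: {m:6.2f} +/- {s:.2f}")

V = matrix.values.to_numpy()
keep = V.std(axis=0) > 0  # the base peak is constant at 100 by construction
C = np.corrcoef(V[:, keep], rowvar=False)
iu = np.triu_indices_from(C, 1)
print(f"\nmedian pairwise inter-ion correlation: {np.median(C[iu]):.3f}")
print("(values above 0.9 are the signature of replicate EI spectra that the")
print(" per-ion linear models exploit; a consensus spectrum ignores it)")
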