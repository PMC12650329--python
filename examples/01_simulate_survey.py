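"""Generate a synthetic hot-spring survey and look at what was planted.

The generator builds metagenomic bins whose proteins contain two
reaction-center families (PufL-like and PufM-like, four clades each), a
divergent PsbA/PsbD-like outgroup, single-ORF PufL-PufM fusions, fragments,
shuffled decoys and five puf operon architectures — all with ground truth.
"""

import collections

from pufminer import SimConfig, generate_dataset

dataset = generate_dataset(SimConfig(rng_seed=1))

families = collections.Counter(t.family for t in dataset.truth.sequences.values())
architectures = collections.Counter(dataset.truth.contigs.values())
n_hot = sum(dataset.truth.bins.values())
n_missing = sum(1 for b in dataset.bins if b.temperature_c is None)

print(f"bins: {len(dataset.bins)} ({n_hot} truly hot, "
      f"{n_missing} without a recorded temperature)")
print(f"proteins: {len(dataset.proteins)}")
print("sequence families planted:", dict(families))
print("operon architectures planted:", dict(sorted(architectures.items())))
print()
print("Each 'fusion' is one ORF carrying a PufL-like and a PufM-like domain;")
print("decoys are shuffled-composition sequences the search must reject.")
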