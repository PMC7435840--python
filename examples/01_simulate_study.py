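"""Simulate the seven-product tablet study and look at what it contains.

Builds the default study design (27 batches, 10 tablets each, including a
falsified illicit-channel product with no API) and prints the per-product
spectrum counts.
"""

from alqc import synthetic

study = synthetic.simulate_study(seed=1)
print(f"{study.n_samples} spectra on a {study.n_points}-point grid "
      f"({study.wavelengths[0]:.0f}-{study.wavelengths[-1]:.0f} nm)\n")

for (brand, channel), subset in study.iter_products():
    n_batches = subset.meta["batch"].nunique()
    print(f"{brand:22s} {channel:8s} {n_batches} batches, {subset.n_samples} spectra")

print("\nEach count is batches x 10 tablets; the illicit-channel Combiart "
      "spectra come from a formulation with zero artemether and lumefantrine.")
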