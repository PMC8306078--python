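"""Generate a synthetic fruit batch and inspect what it contains.

Builds 100 NIR samples (900-1700 nm, 5 nm step) with the default
constituent statistics and Beer-Lambert band library, then prints the
population moments actually achieved and the spectral data shape.
"""
import numpy as np

import fruitspec as fs

config = fs.GeneratorConfig(n_samples=100, region="NIR", seed=42)
batch = fs.generate_batch(config)

print(f"spectra: {batch.spectra.values.shape} "
      f"({batch.spectra.wavelengths[0]:g}-{batch.spectra.wavelengths[-1]:g} nm)")
print(f"reflectance range: {batch.spectra.values.min():.3f} "
      f"to {batch.spectra.values.max():.3f}")
print(f"{'constituent':16s} {'mean':>7s} {'sd':>7s}  unit")
for name in batch.concentrations.constituents:
    v = batch.concentrations.values(name)
    unit = batch.concentrations.units.get(name, "")
    print(f"{name:16s} {v.mean():7.3f} {v.std(ddof=1):7.3f}  {unit}")

# The per-stage means rise for the ripening-linked constituents: later
# maturity stages carry more sugar, acid and vitamin C.
stages = batch.concentrations.stages
ssc = batch.concentrations.values("ssc")
print("\nSSC mean by maturity stage:",
      np.round([ssc[stages == s].mean() for s in range(4)], 2))
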