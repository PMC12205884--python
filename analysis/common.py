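"""Shared configuration for the numbered analysis scripts.

The study configuration: four experimental series of 600 inbred lines
each, 2000 markers on overlapping panels, staged unbalanced trials and a
grain-yield trait calibrated to an entry-mean heritability of 0.85.
Every script reads/writes under ``results/analysis``.
"""

from pathlib import Path

from crossgp.simdata import SimConfig, TraitSpec

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 2024


def study_config(seed: int = SEED) -> SimConfig:
    return SimConfig(
        n_series=4,
        genotypes_per_series=(600, 600, 600, 600),
        n_markers=2000,
        n_locations=6,
        traits=(TraitSpec(name="grain_yield", h2_target=0.85),),
        seed=seed,
    )
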