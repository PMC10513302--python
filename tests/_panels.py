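"""Shared simulated genotype panels for relationship-matrix tests."""

import numpy as np

import palmbreed.genome as gn
from palmbreed.genome import Pedigree, build_genome_map


def simulated_three_generation_panel(seed=17, n_markers=2000):
    """Founders -> 2 generations of random mating, genotyped at many loci."""
    rng = np.random.default_rng(seed)
    gm = build_genome_map(10, 100.0, n_markers, rng=rng)
    ped = Pedigree()
    base = gn.initial_ancestral_population(gm, 24, rng, freq_range=(0.2, 0.8))
    founders = gn.sample_founders(base.haplotypes, 24, ped, rng, "X")
    base_freqs = founders.allele_freqs()
    pops = [founders]
    for g in (1, 2):
        pairs = [tuple(rng.choice(pops[-1].size, 2, replace=False)) for _ in range(30)]
        pops.append(gn.make_offspring_population(pairs, pops[-1], gm, ped, rng, g))
    all_ids = np.concatenate([p.ids for p in pops])
    all_dos = np.concatenate([p.dosages() for p in pops])
    return ped, all_ids, all_dos, base_freqs
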