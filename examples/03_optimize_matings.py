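"""Optimize selection and mating with the simulated-annealing mate selector.

Builds a family-structured candidate cohort (120 candidates in 32 full-sib
families), computes the adaptive inbreeding threshold (c_dF = 25%), runs
the annealer from multiple random restarts, and prints the breeding
characteristics of the optimized solution next to a conventional one.
"""

import numpy as np

from palmbreed.annealing import parallel_restarts
from palmbreed.fixtures import ms_instance
from palmbreed.mating import conventional_mating, solution_stats

inst = ms_instance(rng=np.random.default_rng(5))
thr = inst.threshold
print(f"threshold: F(n)={thr.f_n:.3f}  F_rand={thr.f_rand_next:.3f}  "
      f"F_conv={thr.f_conv_next:.3f}  bound={thr.bound:.3f}")

best, _ = parallel_restarts(inst.problem, inst.config, 99, k=24)
ms_stats = solution_stats(
    best.cross_matrix(inst.problem), inst.ranked_ids,
    families=inst.families, kinship=inst.kinship,
)

conv = conventional_mating(inst.ranked_ids, 16, 32, 4, True, np.random.default_rng(6))
conv_stats = solution_stats(conv, inst.ranked_ids, families=inst.families, kinship=inst.kinship)

print(f"{'':28s}{'mate selection':>16s}{'conventional':>14s}")
for name, attr in [
    ("% selfing", "pct_selfing"),
    ("max rank selected", "max_rank"),
    ("max full sibs / family", "max_fullsibs_per_family"),
    ("corr(rank, n crosses)", "corr_rank_vs_ncross"),
    ("mean rank of selfed", "mean_rank_selfed"),
    ("mean parent-pair kinship", "mean_parent_pair_kinship"),
]:
    a = getattr(ms_stats, attr)
    b = getattr(conv_stats, attr)
    print(f"{name:28s}{a:16.3f}{b:14.3f}")
print()
print("Mate selection reaches beyond the top 16 ranks, concentrates crosses")
print("on the best individuals (strongly negative rank/cross correlation),")
print("selfs mainly the very best, and keeps the parent-pair kinship under")
print("the adaptive bound — the emergent rules of the optimized solution.")
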