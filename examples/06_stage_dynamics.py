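"""Stage-wise rewiring: per-stage networks and the dynamic score.

One planted module is silenced in definite AD, so part of the normal-stage
co-expression disappears across progression and the dynamic score
(1 - overlapNum/normalNum) rises above zero.
"""

from adsexnet import default_config, dynamic_score, simulate_cohort, stage_networks

expr, meta, truth = simulate_cohort(default_config(seed=1, n_subjects_per_sex=80))

for sex in ("male", "female"):
    nets = stage_networks(expr, meta, "frontal pole", sex)
    counts = {s: (n.n_edges if n else "N/A") for s, n in nets.items()}
    rec = dynamic_score(nets, "frontal pole", sex)
    print(f"{sex}: stage edges {counts}")
    print(f"  normalNum={rec.normal_num} overlapNum={rec.overlap_num} "
          f"score={rec.score:.3f}")
# The rewired module contributes ~105 normal-stage edges that vanish in
# definite AD, so the score reflects genuine stage-dependent rewiring
# rather than sampling noise.
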