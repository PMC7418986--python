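"""Turn a categorical food survey into a yearly rating and labels.

Each respondent scores 14 fruit-producing species twice on a 0-4 scale
(plant abundance and fruit production).  The per-species product is
averaged over respondents and summed over species, giving a yearly rating
in [0, 224]; terciles of the observed ratings label years poor / normal /
abundant.
"""

from ursaconflict import (
    SimConfig,
    categorize_years,
    render_observables,
    simulate_truth,
    yearly_ratings,
)

cfg = SimConfig(seed=1)
truth = simulate_truth(cfg)
observed = render_observables(truth, cfg)

ratings = yearly_ratings(observed.food_survey)
labels = categorize_years(ratings)

out = ratings.rename("rating").to_frame()
out["category"] = labels
print(out.head(10).round(1).to_string())
print(f"\nmean rating {ratings.mean():.1f}, range {ratings.min():.1f}-{ratings.max():.1f}")
print("poor-food years:", [int(y) for y in labels.index[labels == 'poor']])
# Poor-food years push bears toward human food sources (more complaints)
# and toward hunters' baits (higher harvest vulnerability).
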