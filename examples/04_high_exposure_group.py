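"""Characterize the top-5% exposure group.

Labels the highest-exposure 5% of a synthetic population generated with
built-in effects (non-office workers, tertiary-industry workers and long
working hours drift toward high-concentration microenvironments), screens
covariates with Fisher's exact test / Welch's t-test at p < 0.1, prunes
collinearity by VIF, and fits the multivariate logistic model with
drop-one likelihood-ratio p-values.
"""

import warnings

from kosem import (
    build_grid, compute_exposures, label_top_fraction, univariate_screen,
    check_collinearity, fit_logistic,
)
from kosem.group_analysis import table2_frame
from kosem.synthetic import (
    CampaignSpec, PopulationSpec, covariates_frame,
    generate_campaign, generate_population,
)

grid = build_grid(generate_campaign(CampaignSpec(
    seed=1, minutes_per_cell={"residential_indoor": 30,
                              "transportation": 12, "other": 25})),
    min_obs_per_cell=5)
diaries, truth = generate_population(PopulationSpec(
    n_subjects=6000, seed=2,
    effects={"job=non_office": 0.8, "industry=tertiary": 1.0,
             "working_hours": 0.028}))

exposures = compute_exposures(diaries, grid).set_index("subject_id")
labeling = label_top_fraction(exposures["exposure_ugm3"], fraction=0.05)
print(f"high exposure group: n={labeling.n_high} "
      f"(threshold {labeling.threshold:.1f} ug/m3), low: n={labeling.n_low}")

cov = covariates_frame(diaries)
screen, selected = univariate_screen(labeling, cov, alpha_in=0.1, seed=0)
print("\nunivariate screen (p < 0.1 enters the model):")
print(screen.sort_values("p_value").to_string(index=False))

vif = check_collinearity(cov, selected, vif_threshold=10.0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = fit_logistic(labeling, cov, vif.retained_variables)
print(f"\nlogistic model on {model.n_obs} complete cases "
      f"({model.n_events} high-exposure events):")
print(table2_frame(model).to_string(index=False))
# odds_ratio = exp(coefficient); lrt_p is the drop-one likelihood-ratio
# p-value for the whole variable. The strongest generated effect (tertiary
# industry) surfaces with a positive coefficient and a small LRT p-value;
# correlated effects (job, hours) share the same schedule tilt and may be
# absorbed by it. Day type enters through its own time-budget differences.
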