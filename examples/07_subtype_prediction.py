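"""Fit the simplified five-feature subtype model and apply it to a new cohort.

The categorical naive Bayes model uses Sig-cluster, CNV-cluster, FAT4
mutation, LRP1B mutation, and the 3-level CCNE1 copy-number state.  It
is validated internally by stratified 10-fold cross-validation on the
discovery cohort, then applied to an independently generated 23-sample
cohort whose layer labels come from its own pipeline run.
"""

import pandas as pd

from gcsubtype import CohortTruth, generate_cohort, predictor_features, run_pipeline
from gcsubtype.predictor import cross_validate, fit_nb, predict

discovery = generate_cohort(CohortTruth(seed=1))
result = run_pipeline(discovery.mutations, discovery.segments, discovery.hla)
features = predictor_features(result)
labels = result.subtype_labels

n_folds = min(10, int(labels.value_counts().min()))
cv = cross_validate(features, labels, n_folds=n_folds, seed=0)
print(f"internal {cv['n_folds']}-fold CV accuracy: {cv['accuracy']:.1%}")

model = fit_nb(features, labels)
print(f"model features: {model.features}; priors over subtypes 1-4: "
      f"{[round(float(p), 2) for p in model.priors]}")

validation_truth = CohortTruth(n_samples=23, seed=2)
for profile, proportion in zip(validation_truth.profiles,
                               (10 / 23, 5 / 23, 3 / 23, 5 / 23)):
    profile.proportion = proportion
validation = generate_cohort(validation_truth)
validation_result = run_pipeline(validation.mutations, validation.segments,
                                 validation.hla)
predicted = predict(model, predictor_features(validation_result))

print(f"\nvalidation cohort (n=23) predicted subtype sizes: "
      f"{predicted['subtype'].value_counts().sort_index().to_dict()}")
truth = pd.Series(validation.truth.subtype_labels,
                  index=validation.truth.sample_ids)
accuracy = (predicted["subtype"].reindex(truth.index) == truth).mean()
print(f"agreement with the planted subtypes: {accuracy:.1%}")
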