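"""Train both MIL learners and annotate unseen images.

A small layered-image dataset is segmented and featurized; per-term
Citation-KNN and GPMIL models are trained on 30% of the images and applied
to three held-out images.  Citation-KNN votes a hard term set; GPMIL also
reports its confidence for each term.
"""

import numpy as np

from skinmil import (LearnerConfig, SyntheticSpec, fit_citation, fit_gpmil,
                     generate_images, images_to_bags, predict_citation,
                     predict_gpmil, split_train_test)

spec = SyntheticSpec(n_images=40, n_terms=4, noise_sd=0.02, seed=21)
images, truth = generate_images(spec)
bags = images_to_bags(images, truth.annotation, [10])[10]
train, test = split_train_test(bags, ratio=0.3, seed=1)

config = LearnerConfig()
models_cknn, models_gp = {}, {}
for term in bags.terms:
    y = train.labels(term)
    models_cknn[term] = fit_citation(train.bags, y, R=config.R, standardize=True)
    models_gp[term] = fit_gpmil(train.bags, y, alpha=config.alpha,
                                standardize=True, term=term)

for bag, truth_row in list(zip(test.bags, test.annotation.values))[:3]:
    true_terms = [t for t, v in zip(bags.terms, truth_row) if v]
    cknn_terms = [t for t in bags.terms
                  if predict_citation(models_cknn[t], bag) == 1]
    gp_preds = {t: predict_gpmil(models_gp[t], bag) for t in bags.terms}
    gp_terms = [f"{t} ({p.probability:.0%})"
                for t, p in gp_preds.items() if p.binary == 1]
    print(f"{bag.image_id}:")
    print(f"  true terms:     {true_terms}")
    print(f"  Citation-KNN:   {cknn_terms}")
    print(f"  GPMIL (>=50%):  {gp_terms}")

# Each line lists the annotation terms assigned to one unseen image; GPMIL's
# percentages are posterior probabilities that the term applies.
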