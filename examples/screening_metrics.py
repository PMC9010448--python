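"""Score a binder/non-binder screening submission with bootstrap CIs.

Builds a ground truth with the published counts (799-fragment library, 47
hits at the acetyl-lysine site, 40 fragments excluded for unusable
diffraction), simulates a submission of known quality, and evaluates it.
"""

from fragchal import (bootstrap_ci, build_ground_truth, evaluate_stage1,
                      hit_rate, make_submission_with_accuracy,
                      random_null_submission)

library = [f"F{i}" for i in range(1, 800)]
gt = build_ground_truth(library, hits=library[:47], excluded=library[47:87],
                        site="kac")
print(f"library {len(library)}, positives {gt.n_positive}, "
      f"negatives {gt.n_negative}, excluded {gt.n_excluded}")
print(f"hit rate: {hit_rate(gt.n_positive, len(library))}%")

# a submission that finds 60% of binders and rejects 90% of non-binders
submission = make_submission_with_accuracy(gt, sensitivity=0.6,
                                           specificity=0.9, seed=1)
m = evaluate_stage1(submission, gt)
print(f"sensitivity {m.sensitivity:.3f}  specificity {m.specificity:.3f}  "
      f"balanced accuracy {m.balanced_accuracy:.3f}")

ci = bootstrap_ci(submission, gt, "balanced_accuracy", n_resamples=10_000,
                  seed=1)
print(f"95% bootstrap CI for balanced accuracy: "
      f"[{ci.lower:.3f}, {ci.upper:.3f}]")

# the null baseline: any label-independent predictor scores ~0.5
null = evaluate_stage1(random_null_submission(gt, p_binder=0.1, seed=1), gt)
print(f"random predictor balanced accuracy: {null.balanced_accuracy:.3f} "
      f"(0.5 = random line)")
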