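"""Pattern features and ideal single-feature observers.

Computes the four candidate features of two contrasting sequences, then
the exact d' of each ideal single-feature observer (likelihood-ratio
rule on the feature's exact distribution over all 2^20 sequences) next
to the full-model ceiling.
"""

from patdet import (
    CONDITIONS,
    exact_feature_distribution,
    exact_performance,
    feature_vector,
    single_feature_classifier,
)

for seq in ("11111111100000011111", "01101001100101101001"):
    fv = feature_vector(seq)
    print(f"{seq}: F1={fv.f1} (longest run), -F2={fv.f2_signed} "
          f"(longest alternation, negated), F3={fv.f3} (repetitions), "
          f"F4={fv.f4} (colour imbalance)")
print()
print("exact d' by observer and condition (larger = better discrimination):")
print("model    LD     MD     HD")
rows = {"full": [], "F1": [], "F2": [], "F3": [], "F4": []}
for name, params in CONDITIONS.items():
    rows["full"].append(exact_performance(params).d_prime)
    for fid in (1, 2, 3, 4):
        clf = single_feature_classifier(exact_feature_distribution(fid, params))
        rows[f"F{fid}"].append(clf.exact_performance().d_prime)
for model, vals in rows.items():
    print(f"{model:5s} " + "  ".join(f"{v:.3f}" for v in vals))
print("No single feature reaches the full model; F3 (repetition count)")
print("comes closest at low disruption.")
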