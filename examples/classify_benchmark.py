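"""Feature ranking and supervised classification on the synthetic benchmark.

Ranks all retained features by average rank over four single-attribute
evaluators x 10 CV folds, then trains random forests on a growing prefix of
the ranking. The accuracy curve shows the hallmark of the method: a single
activation-segment feature is already highly informative, and a handful
saturate the benchmark.
"""

from kinconf.features import extract_matrix, presence_filter
from kinconf.ml import incremental_feature_accuracy, learning_curve, rank_features
from kinconf.synth import standard_benchmark

corpus = standard_benchmark(seed=1, n_per_class=100)
matrix = extract_matrix(corpus.structures, corpus.profile)
matrix.labels = corpus.labels.loc[matrix.values.index]
kept = presence_filter(matrix)
sub = matrix.subset([f.name for f in kept])
sub.labels = matrix.labels

ranked = rank_features(sub, folds=10, seed=1)
print("top 5 features by average rank:")
print(ranked.table["average_rank"].head(5).to_string())

curve = incremental_feature_accuracy(ranked, sub, k_max=5, seed=1)
print("\nhold-out accuracy with top-k features:")
print(curve[["feature_added", "test_accuracy"]].to_string())

lc = learning_curve(sub, train_sizes=[25, 50, 100], repeats=3, seed=1,
                    selected_features=ranked.top(10))
print("\nlearning curve (top-10 features):")
print(lc.to_string())
print("\nAll top features sit in the activation segment: its orientation "
      "alone separates active from inactive conformations.")
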