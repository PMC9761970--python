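"""Catastrophic forgetting vs. the interleaved continual schedule.

Trains two schedules over the same pair of corpora with disjoint relation
labels (an adverse-event corpus, then a chemical-protein corpus):

* sequential continual learning [A then B] — after step B the model's
  relation F1 on A's test set collapses (forgetting);
* continual multi-corpora — A is split in two, step 2 mixes A's second
  half with B, and performance on A survives.

One seed, scaled-down sizes; a few minutes on one CPU.
"""

from spanrel import evaluate_pipeline, generate_corpus
from spanrel.corpus import LabelVocabulary
from spanrel.encoders import TokenVocabulary
from spanrel.synthetic import SyntheticConfig, TrainingSchedule, build_schedule
from spanrel.training import JointModel, TrainConfig, run_schedule

kw = dict(mention_count_dist={1: 1.0}, relation_probability=0.7)
corpus_a = generate_corpus(SyntheticConfig("ade", ("Drug", "Disease"), ("ADE",),
                                           n_sentences=120, seed=1, **kw))
test_a = generate_corpus(SyntheticConfig("ade", ("Drug", "Disease"), ("ADE",),
                                         n_sentences=40, seed=2, **kw))
corpus_b = generate_corpus(SyntheticConfig("cpr", ("Drug", "Protein"), ("CPR",),
                                           n_sentences=120, seed=3, **kw))
vocab = TokenVocabulary.from_corpora([corpus_a, test_a, corpus_b])
cfg = TrainConfig(epochs=12, seed=0)

re_f1 = lambda m: evaluate_pipeline(m, test_a, conditional=False).metrics["RE"]["f1"]

# --- sequential continual learning -----------------------------------------
model = JointModel(vocab, LabelVocabulary(), seed=0)
sched = build_schedule([corpus_a, corpus_b], "continual", seed=0)
model, _, _ = run_schedule(model, TrainingSchedule("continual", sched.steps[:1]), cfg)
post_a = re_f1(model)
model, _, _ = run_schedule(model, TrainingSchedule("continual", sched.steps[1:]), cfg)
final = re_f1(model)
print(f"continual [A->B]: RE F1 on A after step A = {post_a:.3f}, "
      f"after step B = {final:.3f}")

# --- continual multi-corpora ------------------------------------------------
model2 = JointModel(vocab, LabelVocabulary(), seed=0)
sched2 = build_schedule([corpus_a, corpus_b], "continual_multi_corpora", seed=0)
for step in sched2.steps:
    print(f"  {step.name}: " + " + ".join(f"{n}({k})" for n, k in step.sources))
model2, _, _ = run_schedule(model2, sched2, cfg)
print(f"continual multi-corpora: RE F1 on A = {re_f1(model2):.3f}")
# The gap between the two final numbers is the forgetting the interleaved
# schedule (partial data replay) buys back.
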