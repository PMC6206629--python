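"""Type-I-error and power study of the model-choice tests.

Replicates the simulate → fit → test pipeline under the two study
designs: a null design where every genome shares one mismatch probability
(rejections are type I errors) and an alternative where two genomes carry
different probabilities (rejections are power).  20 replicates keep this
example quick; the full-scale study uses 100.
"""

from tadip import run_test_study

null_study = run_test_study(design="fixed", n_reps=20, alpha=0.05, seed=1)
print("fixed-error (null) design — rejection rate = empirical type I error")
print(null_study.summary())

alt_study = run_test_study(design="varying_two", n_reps=20, alpha=0.05, seed=2)
print("varying-two-error design — rejection rate = empirical power")
print(alt_study.summary())
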