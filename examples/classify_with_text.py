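"""The value of clinical text prompts for mimic rejection.

Runs the package's text-ablation study: labelled candidate crops are built
from metadata-coupled phantoms (calcification frequency depends on age and
gender, and half the mimics carry a CMB-like phase signature), then the
multimodal classifier is trained with and without the text branch at matched
seeds and budgets (two initialization seeds per arm, best-epoch selection).
Takes a few minutes on one CPU.
"""

from cmbscreen.experiments import classifier_ablation_experiment

res = classifier_ablation_experiment(seed=1)
print(f"{res['n_candidates']} candidates")
print(f"with text:    validation accuracy {res['with_text']:.2f} "
      f"(runs: {['%.2f' % b for b in res['with_text_runs']]})")
print(f"without text: validation accuracy {res['without_text']:.2f} "
      f"(runs: {['%.2f' % b for b in res['without_text_runs']]})")
print()
print("The image alone cannot resolve phase-ambiguous mimics; the demographic")
print("prior in the prompts (mimics skew young/female here) recovers part of")
print("that gap, mirroring the with/without-text contrast of the full model.")
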