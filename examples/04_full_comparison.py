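"""The full concentration grid: precision/recall trade-off and AUC deltas.

Runs the moderate-potency model at every inference concentration plus
the conventional high-threshold model, and prints the per-model median
high-potency precision/recall together with the fraction of assays
where the method improves RIPtoP-corrected AUC-PR and AUC-ROC.
"""

import warnings

import concshift as cs
from concshift import presets

warnings.filterwarnings("ignore")

dataset = cs.generate_library(presets.default_screen(seed=1))
result = cs.run_comparison(
    dataset,
    train_config=presets.desk_train_config(seed=0),
    criteria=presets.desk_criteria(),
    seed=0,
)

print(f"eligible assays: {len(result.assays)}; "
      f"test compounds: {len(result.test_ids)}")
print(f"{'model':>24}  {'precision':>9}  {'recall':>6}  {'calls':>5}")
for name, sub in result.reports.groupby("model_name", sort=False):
    print(f"{name:>24}  {sub['high_potency_precision'].median():9.3f}  "
          f"{sub['high_potency_recall'].median():6.3f}  "
          f"{sub['p_calls'].median():5.1f}")
print("-> precision rises and recall/Active calls fall as the inference "
      "concentration drops: low-dose profiles only show signal for the "
      "most potent compounds.")

print("\nfraction of assays improved over the conventional "
      f"{'[20 μM / 20 μM / 7]'} model:")
print(result.summary.to_string(index=False,
                               float_format=lambda v: f"{v:.2f}"))
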