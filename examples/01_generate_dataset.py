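"""Generate a synthetic UC trial database with the published pool structure.

Builds the packaged 35-trial design, simulates clinical-remission responder
counts from the packaged final model, and prints the baseline summary table.
The totals row reproduces the published pool margins (for the remission
endpoint, trials of the one drug without a remission model are dropped).
"""

from uc_mbma import load_packaged_model, summarize_dataset, write_dataset
from uc_mbma.synthetic import generate_dataset, paper_design

truth = load_packaged_model("remission")
design = paper_design()
records, arms = generate_dataset(design, truth, seed=42)

print(f"design: {design.n_trials} trials, {design.n_arms} arms, "
      f"{design.n_patients} patients ({design.n_placebo_arms} placebo arms)")
print(f"remission dataset: {len(records)} records across {len(arms)} arms\n")

table = summarize_dataset(arms, records)
print(table[["drug", "trials", "patients", "arms", "duration",
             "prior_tnf_pct"]].to_string(index=False))
print("\nEach drug row: trial/patient/arm counts and median (min, max) of "
      "arm-level covariates in the simulated remission pool.")

write_dataset("remission_synthetic.csv", records, arms)
print("wrote remission_synthetic.csv")
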