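"""The full two-region study: grid, refinement, best-model table.

For each sensor region, runs three pretreatment chains on every in-region
constituent, refines the best chain per constituent with interval
elimination + outlier removal, and prints the best row per constituent in
the prediction-report layout.
"""
import pandas as pd

import fruitspec as fs

CHAINS = ["SM + MC", "SM + 1st Dev + MC", "SM + Log + 1st Dev + MC"]

best_rows = []
for region in ("VIS-NIR", "NIR"):
    batch = fs.generate_batch(
        fs.GeneratorConfig(n_samples=100, region=region, seed=42)
    )
    result = fs.run_grid(
        batch.spectra,
        batch.concentrations,
        chain_codes=CHAINS,
        split_spec=fs.SplitSpec(0.70, seed=42),
        settings=fs.GridSettings(refine="best"),
    )
    for name in batch.concentrations.constituents:
        rows = [r for r in result.reports
                if r.parameter == name and r.rmsep is not None]
        best_rows.append(fs.select_best(rows).to_row())

frame = pd.DataFrame(best_rows)
cols = ["parameter", "region", "pretreatment", "n_variables", "lvs",
        "r2_cal", "r2_cv", "r2_pred", "rmsep"]
pd.set_option("display.width", 200)
print(frame[cols].round(3).to_string(index=False))
# Every constituent with absorption bands inside its region is recovered
# with R2pred >= 0.9; n_variables < 121/161 shows where interval
# elimination trimmed the grid.
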