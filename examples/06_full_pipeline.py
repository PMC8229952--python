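"""Run the complete analysis pipeline on the packaged dataset.

Stages: load -> structures -> 3D embedding -> descriptors -> log response
-> inactive exclusion -> activity split -> GA-MLR -> validation ->
Williams applicability domain -> frozen-model predictions for the two
proposed compounds.  All artifacts land in the output directory.
"""

from dpp3qsar import GAConfig, PipelineConfig, run_paper_pipeline

config = PipelineConfig(
    outdir="pipeline_out",
    n_yscramble=200,
    ga=GAConfig(population_size=50, generations=40, seed=1),
)
result = run_paper_pipeline(config)

print(f"selected descriptors: {list(result.model.descriptor_names)}")
print(f"training R2 = {result.report.R2:.3f}, Q2_LOO = {result.report.Q2_LOO:.3f}")
print(f"split: {len(result.split.training_ids)} training / "
      f"{len(result.split.test_ids)} test, "
      f"outliers removed: {list(result.split.outlier_ids)}")
print(result.predictions[["id", "pred_log_pct_inhibition"]].round(2)
      .to_string(index=False))
print(f"artifacts: {sorted(p.name for p in result.artifacts.values())}")
# The predictions use the frozen published coefficients on re-derived
# descriptors, so their scale reflects this package's descriptor
# conventions rather than the original software's.
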