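"""Run the complete pipeline: simulate -> demodulate -> calibrate -> invert ->
fit -> classify -> rank -> correlate, with provenance.

Every output lands under the run directory as TIFF + JSON sidecars, CSV
tables and JSON reports, and the manifest records seeds, stage status and
checksums; rerunning with the same configuration and seed reproduces the
bundle byte for byte.
"""

from sfdikit import PipelineConfig, run_pipeline

config = PipelineConfig({"classification": {"k": 9, "task": "subtypes"}})
manifest, bundle = run_pipeline(config, seed=1, out_dir="scratch/example_run")

report = bundle["report"]
print(f"stages: {', '.join(f'{k}={v}' for k, v in manifest.stage_status.items())}")
print(f"cross-validated subtype accuracy: {report['accuracy']:.3f}")
print(f"feature ranking: {' > '.join(bundle['ranking']['order'])}")
masked = next(w for w in manifest.warnings if w["stage"] == "invert")
print(f"pixels masked by the R^2 < 0.95 rule: {masked['masked_pixel_fraction']*100:.2f}%")
print(f"outputs + manifest under scratch/example_run ({len(manifest.checksums)} files)")
print("Accuracy here reflects the default class overlap of the generator, not any")
print("clinical performance; rerun with the same seed to get identical checksums.")
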