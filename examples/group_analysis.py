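"""Run the whole pipeline on a small cohort and read the report.

Uses the default ROI amplitude profiles (key + boundary coding in M1,
genuine position coding in premotor cortex, domain-general item-position
coding in hippocampus/perirhinal cortex) with a 10-subject cohort, then
prints the per-ROI coding decisions and the boundary-trimming control.
"""

from seqrsa import PipelineConfig, make_report, run_pipeline

config = PipelineConfig(seed=123, n_subjects=10, n_voxels=40, n_perm=200)
tables = run_pipeline(config, "scratch_pipeline", overwrite=True)
report = make_report("scratch_pipeline")

print("significant coding (Bonferroni over 5 ROIs):")
for key, row in report["coding"].items():
    if row["significant"]:
        print(f"  {key:<16} t = {row['t']}")

print("\nposition coding after removing boundary positions (6x6):")
for roi, row in report["boundary_trimmed"].items():
    flag = "still significant" if row["significant"] else "gone"
    print(f"  {roi:<4} p_corr = {row['p_corrected']:.3f}  ({flag})")

print("\nprotocol checks:", report["protocol_checks"])

# M1's position coding is carried entirely by the boundary pattern, so it
# disappears in the trimmed control while premotor cortex — which has a
# genuine position code planted — survives.
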