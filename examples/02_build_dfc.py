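"""Build a subject's dynamic functional connectivity sequence.

Slides a 5-sample window (15 s at a 3 s sampling interval) in steps of 2
samples over one simulated subject, yielding one absolute-Pearson
connectivity matrix per window.
"""

from dfcdist import SimConfig, SubjectRecord, WindowSpec, build_dfc, generate_subject_series
from dfcdist.cohort import _subject_stream

cfg = SimConfig(n_per_cell=1, n_regions=16, n_timepoints=90, seed=7)
record = SubjectRecord("sub-demo", age=71.0, sex="F", diagnosis="NC")
ts = generate_subject_series(record, cfg, _subject_stream(cfg, 0))

spec = WindowSpec()  # window 5 samples, step 2, drop first/last windows
seq = build_dfc(ts, spec)
first = seq[0].entries

print(f"series: {ts.n_timepoints} timepoints x {ts.n_regions} regions")
print(f"windows: {len(seq)} connectivity matrices "
      f"(43 complete, minus first and last)")
print(f"each window spans {spec.window_size * ts.sampling_interval_s:.0f} s, "
      f"offset {spec.step * ts.sampling_interval_s:.0f} s")
print(f"matrix checks: symmetric={bool((first == first.T).all())}, "
      f"hollow={bool((first.diagonal() == 0).all())}, "
      f"edges in [{first.min():.2f}, {first.max():.2f}]")
# 90 timepoints -> 43 complete windows -> 41 kept; every matrix is a valid
# absolute-correlation connectivity matrix.
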