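"""Summarise per-lesion fusion-accuracy and cohort values.

Feeds reported per-patient values (five Dice coefficients, scan-to-biopsy
intervals, and site-wise tumour volumes) through the same summary routine
the fusion report uses, printing median and range.  An undefined Dice
(tumour edge not visible on ultrasound) is carried as a first-class state
and excluded from the median rather than counted as zero.
"""

import habitatmap as hm

report = hm.DSCReport(per_lesion=(
    ("patient 1", "omentum", None),   # tumour edge not visible on B-mode US
    ("patient 2", "pelvis", 0.76),
    ("patient 3", "omentum", 0.37),
    ("patient 4", "omentum", 0.43),
    ("patient 5", "pelvis", 0.79),
    ("patient 6", "omentum", 0.53),
))
median, lo, hi = report.summary()
print(f"fusion accuracy over defined lesions: median DSC {median:.2f} "
      f"(range {lo:.2f}-{hi:.2f})")

days = [30, 10, 29, 16, 7, 26]
m, lo, hi = hm.summarize(days)
print(f"scan-to-biopsy interval: median {m:.0f} days (range {lo:.0f}-{hi:.0f})")

omental = [15.7, 295.2, 19.4, 187.4]
pelvic = [591.7, 448.3]
m_o = hm.summarize(omental)[0]
m_p = hm.summarize(pelvic)[0]
print(f"tumour volumes: omental median {m_o:.1f} cm^3, "
      f"pelvic median {m_p:.1f} cm^3 - "
      "larger pelvic masses fuse more accurately than small omental deposits")
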