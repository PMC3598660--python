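"""Replicate QC: the late-amplification filter, contamination verdicts, CV.

Replicate Cq values above the cutoff (default 35 cycles) are excluded one
well at a time before averaging, negative controls are judged against the
same cutoff, and the coefficient of variation quantifies technical noise.
"""

from refstab import (
    CqObservation,
    CqTable,
    aggregate_replicates,
    coefficient_of_variation,
    flag_contamination,
)

observations = [
    # a clean triplicate
    CqObservation("GUSB", "cells1", 1, "run1", 24.01),
    CqObservation("GUSB", "cells1", 2, "run1", 24.12),
    CqObservation("GUSB", "cells1", 3, "run1", 23.95),
    # one good well, two late wells that the filter should drop
    CqObservation("TBP", "cells1", 1, "run1", 34.9),
    CqObservation("TBP", "cells1", 2, "run1", 35.2),
    CqObservation("TBP", "cells1", 3, "run1", 36.1),
    # negative controls: a late NTC (negligible) and an early no-RT (fail)
    CqObservation("GUSB", "ntc", 1, "run1", 37.4, "no_template_control"),
    CqObservation("TBP", "nrt", 1, "run1", 28.0, "no_rt_control"),
]
table = CqTable(observations=observations)

matrix, flags = aggregate_replicates(table, max_cq=35)
print("mean Cq after filtering:")
print(matrix.mean_cq.round(3))
print(f"replicates used: GUSB={matrix.n_used.loc['GUSB', 'cells1']},"
      f" TBP={matrix.n_used.loc['TBP', 'cells1']}")
for gene, sample, rep, reason in flags.excluded_observations:
    print(f"excluded {gene}/{sample} replicate {rep}: {reason}")

for gene, control, cq, verdict in flag_contamination(table).contamination:
    print(f"control {control} for {gene}: Cq {cq} -> {verdict}")

cv = coefficient_of_variation([24.01, 24.12, 23.95])
print(f"intra-assay CV of the GUSB triplicate: {cv:.2f}%")
# TBP's mean is 34.9 (only the sub-cutoff well survives); a failing no-RT
# control means genomic-DNA carry-through and is reported, not auto-excluded.
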