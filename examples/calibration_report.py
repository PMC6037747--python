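"""Inspect the shipped calibration artifact.

The four EEP trafficking rates are the only fitted parameters of the model;
everything else (binding constants, copy numbers, geometry) is fixed.  This
prints the fitted rates, the calibration targets with their achieved
mean-field values, and the mean-field prediction for every reference
benchmark, flagging where the compartmental surrogate is biased relative to
the reported value (those benchmarks are validated at a doubled tolerance).
"""

import json

from spinetraffic.calibration import FREE_PARAMS, load_report
from spinetraffic.network import calibrated_parameters

params = calibrated_parameters()
print("calibrated trafficking rates:")
for k in FREE_PARAMS:
    print(f"  {k} = {getattr(params, k):.4g}")

report = load_report()
print(f"\ncalibration feasible: {report['feasible']}")
print("\ntargets (mean-field):")
for row in report["targets"]:
    print(f"  {row['name']:24s} target {row['target']:8.2f}  "
          f"achieved {row['achieved']:8.2f}  within: {row['within_tolerance']}")

print("\nbenchmark predictions vs reported values:")
for row in report["benchmarks"]:
    flag = "" if row["within_1std"] else "  <- surrogate bias (2-STD validation)"
    std = row["reported_std"]
    std_s = f"+/- {std}" if std is not None else f"band {row['band']}"
    print(f"  {row['name']:24s} reported {row['reported_mean']:8.2f} {std_s:14s} "
          f"predicted {row['meanfield_prediction']:8.2f}{flag}")
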