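"""Soft restrictions: unlikely age/tumour-type combinations warn, not error.

A hepatoblastoma at age ten is rare but not impossible, so the engine keeps
the record consistent and reports the contradicted inherited age bound.
"""
import crcheck as cc
from crcheck.core_dictionary import CancerCaseRecord

tbox = cc.build_tbox()

rec = CancerCaseRecord(patient_id="P2", tumour_id="T2", morphology="8970",
                       behaviour="3", age_at_diagnosis=10)
report = cc.validate_record(rec, tbox)
print("hepatoblastoma (8970/3) at age 10:")
print(f"  status = {report.record_status}")
print(f"  morphology-behaviour = {dict(report.inferences)['morph_behaviour']}")
for f in report.warnings:
    print(f"  WARNING {f.rule_id}: {f.message}")
# The record stays consistent (no empty set); the inherited restriction
# "age < 6" merely contradicts the asserted age of ten.

for morphology, extra in [("8970", {}), ("9064", {"topography": "C649"})]:
    free = [a for a in range(21) if not cc.validate_record(
        CancerCaseRecord(patient_id="P", tumour_id="T", morphology=morphology,
                         behaviour="3", age_at_diagnosis=a, **extra),
        tbox).warnings]
    print(f"morphology {morphology}: max warning-free age = {max(free)}")
# Prints 5 for hepatoblastoma and 7 for the germ-cell rule - the coded
# "unlikely above age N" bounds of the shipped rules.
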