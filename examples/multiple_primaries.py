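"""Multiple-primary detection for one patient's registrations.

Three cases: trachea C33/8550, lung C34/8140, colon C18/8936. The first
two share both the site group and the histology group, so they count as a
single primary; the colon case is independent.
"""
import crcheck as cc
from crcheck.core_dictionary import CancerCaseRecord

term = cc.load_default_terminology()

cases = tuple(
    CancerCaseRecord(patient_id="PY", tumour_id=f"Y{i}", topography=t,
                     morphology=m, behaviour="3")
    for i, (t, m) in enumerate(
        [("C33", "8550"), ("C34", "8140"), ("C18", "8936")], start=1))

partition = cc.detect_multiple_primaries(cc.PatientCaseSet("PY", cases),
                                         term.group_table)
print("independent primaries:", partition.groups)
for f in partition.findings:
    print(f"  {f.severity} {f.rule_id}: {f.message}")
# Partition (('Y1', 'Y2'), ('Y3',)): counting Y1 and Y2 separately would
# overstate incidence, so the pair is flagged as a suspected duplicate.
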