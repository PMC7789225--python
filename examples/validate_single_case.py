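"""Validate one registry case through the three scenarios.

Builds the in-situ/clinical-BoD contradiction, shows the hard error and its
explanation, then corrects the behaviour code and shows the confirmed code.
"""
import crcheck as cc
from crcheck.core_dictionary import CancerCaseRecord

tbox = cc.build_tbox()

bad = CancerCaseRecord(patient_id="P1", tumour_id="T1", morphology="8720",
                       behaviour="2", basis_of_diagnosis="1")
report = cc.validate_record(bad, tbox)
print("melanoma, in-situ behaviour, clinical basis of diagnosis:")
print(f"  status = {report.record_status}")
for f in report.findings:
    print(f"  {f.severity} {f.rule_id}: {f.message} (axioms: {list(f.explanation)})")
# The ERROR means the code combination denotes an empty class: an in-situ
# tumour must have been diagnosed by cytology or histology.

fixed = CancerCaseRecord(patient_id="P1", tumour_id="T1", morphology="8720",
                         behaviour="3", basis_of_diagnosis="1")
report2 = cc.validate_record(fixed, tbox)
print("\nafter correcting behaviour to malignant/primary:")
print(f"  status = {report2.record_status}")
print(f"  basis_of_diagnosis confirmed by {report2.confirmed('basis_of_diagnosis')}")
# The defined class ENCRBoD_1 now subsumes the record, confirming the code.
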