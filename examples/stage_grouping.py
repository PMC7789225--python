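"""TNM ed.6 stage-group inference from a fully described case.

A urinary-bladder carcinoma (T3 N0 M0) resolves to stage group III via the
TNM topography grouping; the same report carries every other terminological
inference plus the unconfirmed basis-of-diagnosis code.
"""
import crcheck as cc
from crcheck.core_dictionary import CancerCaseRecord, PartialDate

dictionary = cc.load_default_dictionary()
tbox = cc.build_tbox()

case = CancerCaseRecord(
    patient_id="PX", tumour_id="X1", sex="1",
    birth_date=PartialDate(1950, 3, 14), incidence_date=PartialDate(2003, 6, 2),
    registration_date=PartialDate(2003, 7, 1),
    last_vital_status_date=PartialDate(2004, 6, 2),
    age_at_diagnosis=53, topography="C679", morphology="8071", behaviour="3",
    grade="2", basis_of_diagnosis="1", extent_of_disease="1",
    tnm_t="T3", tnm_n="N0", tnm_m="M0", vital_status="1",
    survival_duration=366,
    extras=(("geo_code", "EU1"), ("icdo_edition", "3"), ("registry_id", "R1")))

report = cc.validate_record(case, tbox, dictionary=dictionary)
print(f"status = {report.record_status}")
for kind, value in report.inferences:
    print(f"  inferred {kind} = {value}")
for field, cls in report.confirmed_codes:
    print(f"  confirmed {field} via {cls}")
for f in report.unconfirmed:
    print(f"  UNCONFIRMED {f.fields[0]}: candidates {list(f.explanation)}")
# stage_group = III because T3 N0 M0 falls in the stage-III row of the
# bladder table; basis_of_diagnosis stays unconfirmed because clinical BoD
# only admits a restricted morphology list (not 8071).
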