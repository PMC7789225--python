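# crcheck

Ontology-based validation of European cancer-registry core data.

Population-based cancer registries feed harmonised European incidence,
mortality and survival statistics, and the quality of those indicators
stands or falls with the validity of the registered core variables:
ICD-O-3 topography, morphology and behaviour, basis of diagnosis, grade,
extent of disease, TNM stage, dates and follow-up. `crcheck` is for
registry data managers and epidemiologists who want those edit checks
expressed as a formal, declarative axiom base rather than scattered
procedural code, so that the rule base and the data model cannot drift
apart and every rejection comes with a machine-readable explanation.

## The model

Each tumour record is translated into a conjunctive class expression — one
singleton value restriction per coded field, a point interval for age, plus
the named classes the terminology resolves for it (morphology family,
morphology-behaviour, tumour type, TNM topography grouping):

```text
Record ≡ ∃bod.{1} ⊓ ∃morphology.{8071} ⊓ ∃behaviour.{3} ⊓ ∃age.[53,53] ⊓ …
```

Validation rules compile onto three axiom shapes over such expressions:

1. **Hard rules** — impossible combinations — become disjointness axioms.
   `∃behaviour.{2} ⊓ ∃bod.¬{5,7} ⊑ ⊥`: an in-situ tumour whose basis of
   diagnosis is neither cytology nor histology denotes the empty class.
   A record subsumed by such a class yields an **ERROR** with a minimal
   explaining axiom set.
2. **Soft rules** — unlikely combinations — become subclass restrictions.
   `Hepatoblastoma ⊑ ∃age.(≤ 5)`: a hepatoblastoma record at age ten stays
   consistent but the inherited bound contradicts the asserted age, which
   yields a **WARNING**.
3. **Defined classes** — necessary *and* sufficient conditions for an
   assigned code. `ENCRBoD_1 ≡ ∃bod.{1} ⊓ ∃morphology.{8000,8720,9140,9590,9800}
   ⊓ ∃behaviour.¬{2}`: a record matching the definition has its code
   *confirmed*; a guarded code no definition subsumes is reported
   **UNCONFIRMED** — the closed-world reading of a reasoner's silence.

Subsumption and consistency are decided structurally over finite attribute
domains (with case-splitting along axiom-antecedent boundaries, which makes
the procedure equivalent to exhaustive model enumeration on this fragment).
On top sit TNM ed.6 stage-group inference, grouping-based multiple-primary
detection, a format pre-processing stage, batch file processing and an OWL
functional-syntax export of the whole axiom base.

## Worked example

```python
import crcheck as cc
from crcheck.core_dictionary import CancerCaseRecord

tbox = cc.build_tbox()   # shipped dictionary + terminology + rules

rec = CancerCaseRecord(patient_id="P1", tumour_id="T1",
                       morphology="8720", behaviour="2",
                       basis_of_diagnosis="1")
report = cc.validate_record(rec, tbox)
print(report.record_status)                  # INVALID
print(report.findings[0].rule_id,
      list(report.findings[0].explanation))  # R1 ['R1']
```

The melanoma record claims in-situ behaviour with a clinical basis of
diagnosis — rule R1's disjointness axiom makes it an empty class, so the
report carries one ERROR whose explanation cites exactly `R1`. Correcting
`behaviour="3"` flips the status to `VALID` and the report instead shows
`basis_of_diagnosis` confirmed by the defined class `ENCRBoD_1`.

The comprehensively described bladder case (`examples/stage_grouping.py`)
prints the full inference battery:

```text
status = VALID_WITH_WARNINGS
  inferred tumour_type = TumourTypeUrinaryBladder
  inferred morph_behaviour_group = CarcinomaNOSGroupMorphBeh
  inferred stage_group = III
  inferred casetypecomplete = CaseTypeComplete
  confirmed extent_of_disease via ENCRExtentOfDisease
  confirmed vital_status via ENCRVitalStatusAlive
  UNCONFIRMED basis_of_diagnosis: candidates ['ENCRBoD_1']
```

T3 N0 M0 on a bladder topography resolves to stage group III through the
TNM ed.6 grouping table, while the clinical basis-of-diagnosis code stays
unconfirmed because code 1 only admits a restricted morphology list.

Each script under `examples/` demonstrates one capability (single-case
validation, soft age bounds, stage grouping, multiple primaries, batch +
OWL export) and prints what the numbers mean. The same functionality is
available from the shell:

```bash
crcheck validate cases.csv --error-log errors.csv
crcheck explain cases.csv --row 3
crcheck gen-fixtures demo.csv --n 100 --seed 1 --corrupt-rule R1
crcheck export-owl rules.ofn
```

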