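# Methods

## Problem setting

European cancer registries submit a harmonised core data set — one row per
tumour registration — that is validated centrally before indicator
computation. The validation rules are inter-variable dependency checks:
impossible code combinations (errors), unlikely ones (warnings), and
per-code admissibility conditions (valid basis-of-diagnosis, grade,
morphology/topography pairings). `crcheck` expresses those rules as a
terminological axiom base over a concept taxonomy and validates records by
structural subsumption, so that a single declarative artefact carries both
the data model and the checks.

## Record model and dictionary

The shipped dictionary describes 55 individual variables, 23 of them
mandatory. Four dates (birth, incidence, registration, last known vital
status) are stored as day/month/year part variables sharing a date group;
the incidence date additionally carries an optional precision flag in the
same group. Collapsing every date group to one logical field leaves 46
logical variables (17 mandatory) — the flag variable is what reconciles the
two counts, since groups of exactly three parts can only change the total
by an even number. Variables beyond those named in the published
recommendations complete the call-protocol shape (identifiers, TNM
clinical/pathological variants, treatment summary flags) and their code
lists are marked provisional.

Parsing is a strict pre-processing stage: missing mandatory variables,
typographic errors (non-numeric morphology, malformed topography), codes
outside their domain and impossible date parts all produce FORMAT findings,
and a format-rejected row never reaches the semantic engine. Topography is
accepted with or without the ICD-O print dot and stored dotless. Unknown
date parts are explicit `None` markers, never sentinel numerals.
Pathological TNM categories are preferred over clinical ones for staging;
the prefix is stripped for lookups and kept in the raw row.

## The description-logic fragment

The validation scenarios need only a small fragment: conjunctions of named
classes (atoms), enumerated in/not-in value sets per record attribute, and
closed integer intervals (age); axioms are SubClassOf, DisjointClasses
(a single-member disjoint marks an empty class) and EquivalentClass
(defined classes). No inverse roles, no cardinality restrictions, no
nominals beyond the enumerated datatype sets — a deliberate reduction: the
shipped rule categories never exercise more, and staying inside the
fragment keeps the decision procedure complete and fast.

Attribute domains are finite and read closed-world (topography C000–C809,
morphology 8000–9989, the dictionary code lists, age as `[0, ∞)`), which is
what turns defined-class confirmation into a decidable check without
open-world workarounds: an attribute a rule constrains but the record does
not assert ranges over its whole domain, so an unasserted field can never
confirm a guarded code.

The decision procedure closes a record expression under the hard axioms
and case-splits whenever an axiom antecedent *partially* overlaps the
current allowed value set of some attribute, so that at every leaf each
axiom either definitely fires or definitely cannot. A leaf is dead when an
allowed set becomes empty or a disjointness axiom applies; the expression
is inconsistent iff all leaves are dead, and `general` subsumes `specific`
iff every live leaf of `specific` satisfies `general`. Splitting matters
for completeness: two axioms whose antecedents partition a domain can
jointly entail a consequence that no single firing produces. The test suite
checks the procedure against exhaustive model enumeration on hundreds of
random axiom bases. Record expressions keep all sets singleton, so in the
common case no splitting happens at all and validation is linear in the
rule count.

Soft (WARNING-severity) axioms are excluded from this closure. Including
them would make an over-age hepatoblastoma record *inconsistent*, i.e. a
hard error; instead the validator checks each inherited soft restriction
against the *asserted* values only and reports a contradiction as a
warning. Asserted-only evaluation keeps every warning explainable directly
from the input record, at the cost of not chaining warnings through other
rules' consequences.

Explanations for inconsistencies are minimal axiom sets: the axioms fired
on the dead branches are minimised by deletion (the explanation alone still
proves the clash, and dropping any cited axiom restores consistency), and
all minimal explanations are enumerated via a bounded hitting-set walk.
One ERROR finding is emitted per minimal explanation.

## Rule compilation

The rule file is the single source of truth; the TBox is always derived
from it, and `decompile` inverts the compilation exactly (pinned by test).
Scenario determines the axiom form: HARD_DISJOINT → single-member
DisjointClasses (ERROR), SOFT_RESTRICTION → SubClassOf with WARNING
severity, DEFINED_CODE → EquivalentClass plus a guard `(field, codes)`.
Guards are per-code, not per-field: a record is only tested against the
confirmation classes registered for the specific code value it carries, so
codes with no shipped rule (e.g. basis of diagnosis 5) are simply not
guarded. Code ranges in rules (`9060-9065`, `C00-C55`) expand at load time
against the full format-valid domains; three-character topography endpoints
cover all their sub-sites, and the germ-cell site ranges deliberately skip
the intracranial window C751–C753.

Severity policy: impossibilities (in-situ vs basis of diagnosis) are
errors; "unlikely" categories (age/tumour-type, sex/topography) are
warnings; each shipped rule records whether that level is stated by the
source recommendation or assumed. The rule set ships one exemplar per
published category (R1–R9) plus two defined classes (R10 vital status, R11
extent of disease) so that the full confirmation battery of a
comprehensively described case is exercisable; the extent-of-disease /
behaviour / TNM combination tables exist as a rule kind without shipped
rows. "Clinical investigation" is mapped to basis-of-diagnosis code 2,
distinct from code 1 "Clinical".

## Terminology

Concepts are named classes with parent links forming a DAG (cycles are a
load error); ancestor queries are transitive closures. Shipped content
covers the fixtures the rules and tests need: topography groupings, 3-digit
morphology families over their 4-digit codes, morphology-behaviour classes
grouped SEER-style, tumour types as (topography grouping ×
morphology-behaviour) rows, and TNM ed.6 topography groupings with stage
tables for larynx, urinary bladder, trachea/lung and colorectum. The ed.6
larynx grouping {C320, C321, C322, C101} deliberately differs from the
larynx topography grouping {C320–C322, C323, C328, C329}; the model keeps
both entities rather than hypothetically aligning them. Stage tables are
row lists evaluated in order (first match wins — rows are mutually
consistent, the order only arbitrates overlapping any-T/any-N rows);
stages are integers 0–4 with an optional sub-stage suffix, rendered as
Roman numerals. Combinations outside a grouping's stageable categories —
including unsuffixed bladder T4, whose a/b split decides between stages III
and IV — return an explicit unstageable outcome, never an exception.
In-situ categories (Tis, Ta) are only considered stageable with N0 M0.

## Multiple primaries

One patient's cases merge into a single primary when their topography codes
share a site group *and* their morphology codes share a histology group
(site groups keyed by 3-character prefix, histology groups expanded from
code ranges). The merge relation is an equivalence closure computed by
union-find and cross-checked against a naive transitive-closure oracle.
Cases with unmapped codes form singletons with an UNCONFIRMED finding.
Multi-case groups are flagged, never auto-merged — whether to merge is
registry policy. Timing windows, behaviour transitions and laterality from
the full international multiple-primary rules are out of scope; behaviour
is carried but unused.

## Validation outcomes and batch processing

A report carries findings (ERROR / WARNING / UNCONFIRMED / FORMAT, each
with rule id, involved fields and explanation), confirmed codes, and
terminological inferences (morphology-behaviour and its group, tumour type,
TNM grouping, stage group, most-specific classification, completeness).
Completeness is computed from the dictionary's mandatory list rather than a
dedicated defined class — observably equivalent and cheaper. By default an
UNCONFIRMED finding leaves the record `VALID_WITH_WARNINGS`; the
`escalate_unconfirmed` flag (CLI `--escalate-unconfirmed`) promotes it to
`INVALID` for registries that treat unconfirmed codes as rejections.
Inconsistent records report only their ERRORs: classification and
confirmation presuppose a consistent expression.

Calendar checks run outside the engine: date ordering (birth ≤ incidence ≤
last vital status, on the decidable part of partial dates), age versus
birth/incidence years (completed years, ±1 year tolerance — the value is
configurable since no tolerance is prescribed), and survival duration
versus calendar day count (±31 days, configurable).

Batch processing streams the file in chunks (default batch size 1000,
bounded memory), pre-processes, validates, and writes one delimited
error-log row per finding ordered by input row then rule id. Summaries
satisfy read = valid + warnings + invalid + format-rejected, and results
are independent of batch size (pinned by test). The optional
multiple-primary pass buffers only the per-patient case keys.

## Synthetic data

The generator emits terminology-consistent records from five tumour
templates (skin melanoma with clinical BoD, hepatocellular carcinoma,
staged bladder carcinoma, lung adenocarcinoma, renal cell carcinoma) with
ages 20–85 (inside every soft bound), incidence years 1995–2015, ordered
dates and an exactly consistent survival duration; all guarded codes are
confirmable, so a valid record validates with zero findings. Corruption
mutates a record minimally so that exactly the named rule fires —
collateral fields (birth year when age changes, TNM when topography
changes) are adjusted so no other finding appears — and labels the record
with the expected (severity, rule id). The vital-status rule admits no
violating mutation under its shipped guard and raises a generator error.
Records are structurally, not epidemiologically, representative: passing
round-trips show the engine recovers injected violations exactly, not that
real registry error profiles look like this.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to exercise every pathway while
staying desk-scale: 600 random axiom bases for the model-enumeration
equivalence suite (domains of 3–5 values, 5 atoms — small enough to
enumerate all interpretations exactly), 1000 records per rule for the
synthetic round-trips, 80–400 records for batch properties, and age sweeps
over 0–20 years for the coded bounds. Age thresholds compile as integer
bounds: "unlikely above age 5" becomes `age ≤ 5` (violation from 6),
"greater than 7" becomes `age ≤ 7` (violation from 8), "implication for age
greater than five" becomes `age ≥ 6` (violation up to 5). Ordering is
deterministic everywhere: findings sort by severity class, rule id, then
fields; partitions and candidate lists sort lexicographically.

## Known limitations

The shipped rule and terminology fixtures are exemplars, one per published
rule category — the complete ENCR rule tables and the full ICD-O-3/TNM
transcriptions (thousands of classes) are schema-supported but not
included. TNM editions 7/8 have no tables. The OWL importer reads only the
fragment the exporter emits. No pseudonymisation, record linkage,
cross-patient duplicate detection, or automatic error correction — the
engine exposes asserted versus inferred hierarchies so a future corrector
could exploit them.
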