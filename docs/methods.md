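# Methods

## The integration model

DICOM organizes imaging metadata hierarchically (patient → study → series →
instance) as tagged key–value attributes. Three parts of the standard define
the terminology this package converts into an OMOP CDM vocabulary:

* **Part 6** — the data dictionary: one row per attribute with its (group,
  element) tag, name, keyword and Value Representation (VR). Tags are stored
  canonically as 8 uppercase hex digits; `(gggg,eeee)` is presentation only.
  Retired attributes are loaded and treated like active ones.
* **Part 16** — context groups (CIDs): value sets of coded triplets
  *(code value, coding scheme, code meaning)*. Codes managed by DICOM carry
  scheme `DCM`; codes borrowed from SNOMED/LOINC keep their own schemes, get
  **no** custom concepts, and are reachable only through an external-concept
  resolver (OMOP already assigns them ids). Part 16 also carries the
  Body Part Examined → SNOMED cross-map.
* **Part 3** — per-attribute Enumerated Values / Defined Terms (code-string
  constraints such as the Modality and Patient Position value lists).

The official DocBook XML is not parsed. Ingestion targets a five-file
normalized interchange format (`attributes.csv`, `cid_members.csv`,
`bodypart_map.csv`, `part3_terms.csv`, `constraints.csv`) with validation
implemented directly in the loaders: column contracts, the 8-hex tag
pattern, the full two-letter VR code set (unknown VRs are errors, not
warnings), and referential integrity of every attribute reference. An
adapter from the official sources to this format is future work.

### Vocabulary construction

1. Attributes with nonempty names become `Attribute`-class concepts
   (nameless dictionary rows are placeholders and are excluded, logged).
2. `DCM` occurrences are collapsed by (scheme, code) with CID memberships
   unioned. A Part-3 term whose value string exactly (case-sensitively)
   equals an existing DCM code value is dropped as a duplicate; DICOM code
   strings are uppercase by convention, so no case folding is applied.
   Surviving terms become `Value` concepts keyed `tag:value_string`; DCM
   codes are keyed `DCM:code`. The three key shapes cannot collide.
3. Concept ids are consecutive integers from `id_base` (default
   2 128 000 000, the OMOP-reserved custom range). Payloads are ordered
   deterministically — attributes by tag, then DCM values by (scheme, code),
   then term values by (attribute_tag, value_string) — so reruns reproduce
   identical ids. All concepts are non-standard (`standard_concept` empty).
4. Relationships: each CID constraint contributes one `Maps to value` per
   DCM member of that context group; each term-list constraint contributes
   one per term, targeting the term's own concept or, for dropped
   duplicates, its DCM twin — deduplication removes the redundant *concept*,
   not the attribute→value *mapping*. Each body-part cross-map row whose
   code string has a value concept and whose SNOMED code the resolver knows
   contributes one `Maps to`; unresolvable rows are logged and skipped,
   never fatal.
5. The summary counts values by concept-code prefix and, following the
   field's reporting convention, counts relationship rows toward the
   vocabulary grand total even though they are emitted only in
   `CONCEPT_RELATIONSHIP.csv`. All subtotal identities are asserted on
   every build.

### Harvest and filter

One representative instance per series: lowest Instance Number, ties broken
by lexicographic file path (the choice is arbitrary but must be
deterministic; any instance of a series shares the series-level header).
Top-level elements only — sequences are not descended (VR `SQ` is outside
the whitelist, so nested anatomic codes are unavailable; a known
limitation), private odd-group tags and pixel-data tags are excluded, and
binary-buffer VRs (OB/OW/OD/OF/OL/OV/UN) are skipped because a harvested
value is defined as scalar text. Multi-valued attributes expand to one
element per value with a 0-based `value_index`. Values are decoded per the
file's specific character set with replacement on failure; one bad file
must not abort a harvest.

The filter keeps an element iff its trimmed value (whitespace and trailing
null padding stripped) is nonempty and its VR is in
`{AT, CS, DA, DT, DS, FL, FD, IS, SL, SS, SV, TM, UL, US, UV}` — numeric
and coded representations — or its tag is Manufacturer (0008,0070), the one
free-text field kept because cohort definitions need it. Drop counts are
logged by reason (empty vs VR) since the two causes are worth monitoring
separately in real data.

### CDM loading

Study → Procedure_occurrence (date = Study Date), series →
Image_occurrence (date = Series Date, which also serves as
measurement_date), kept element → one Image_feature + Measurement pair.
`value_as_number` is populated only when the VR is numeric
(DS/IS/FL/FD/SL/SS/SV/UL/US/UV) and the text parses; coded strings (CS/AT)
try a `Maps to value` lookup into `value_as_concept_id`; the two are never
both set. DA/DT/TM values are stored in `value_source_value` only — they
pass the VR filter but have no defensible numeric encoding. Unresolvable
modality or body-part strings map to concept 0 rather than failing, because
manufacturer practice in these fields is inconsistent. Units are not
populated (TR/TE/TI are implicitly milliseconds in DICOM); a known gap.
`measurement_source_value` carries the element's tag so criteria can be
stated without a vocabulary join.

### Cohort semantics

Definitions are conjunctions evaluated with **series-scoped** semantics: all
criteria must hold within a single series. This is the stricter reading and
the protocol-faithful one — TR, TE and TI criteria describe one acquisition.
Anti-monotonicity (adding a criterion never enlarges the result) follows and
is tested. Evaluation is store-agnostic: the generated SQL (one EXISTS
subquery per criterion, joining Measurement through Image_feature) is tested
to agree exactly with the in-memory path. Criteria on DA/TM attributes are
not supported. The shipped T1-volumetric template (TR 2100–2500 ms,
TE 2–4 ms, TI present) is calibrated to this package's synthetic fixtures
and is a configuration default, not a clinical reference range.

## Synthetic data: what it emulates, what it does not

**Standard fixture.** The default ("table2") profile reproduces the
published category totals of a DICOM Standard release: 5190 attributes
(7 nameless → 5183 concepts), 5223 DCM context-group occurrences over 3281
distinct codes, 398 body-part cross-map rows, Part-3 term counts
79/318/16/8 with 74 Modality duplicates, 7101 CID-derived and 739
term-derived `Maps to value`, and 307 SNOMED `Maps to`. Two of those totals
under-determine the underlying structure, and the profile fixes one
admissible layout of each:

* *Repetition plan*: 5223 occurrences / 3281 distinct / 1063 repeated is
  satisfied by 2218 codes in one CID, 879 in three, and 184 in two
  (2218 + 879·3 + 184·2 = 5223; 879 + 184 = 1063).
* *Constraint plan*: the CID-derived mapping total exceeds the occurrence
  total, so some context groups must constrain more than one attribute. The
  generator constrains every CID once (5223) and greedily re-constrains the
  largest CIDs (879 + 879 + 120) to land on 7101 exactly; the layout places
  one 120-member singles bucket for this purpose.
* *Term-derived mappings*: the four named term attributes account for only
  79 + 318 + 16 + 8 = 421 term rows, while the term-derived mapping total
  is 739. The profile therefore adds 318 further Part-3 term rows, on an
  auxiliary attribute, whose values duplicate CID codes: they create no new
  concepts (total values stay 3628) but contribute one mapping each —
  consistent with term extraction having covered more attributes than the
  four named ones.

The fixture's synthetic code values are numeric strings disjoint from its
alphabetic term values, so exact-match deduplication drops exactly the
planned duplicates. The SNOMED resolver stub resolves exactly 307 body-part
rows; 11 rows carry unknown or missing SNOMED codes and 80 rows have no
DICOM code string, exercising the skip paths.

Because these counts are structural, the build's headline numbers are
seed-invariant; the seed shuffles row order (exercising
order-insensitivity) and nothing else.

**DICOM fixture.** Emulates volumetric brain-MR study data at desk scale —
default 5 patients × 8 series × 3 instances (the study-scale equivalent was
545 studies / 4756 series, reduced so the suite runs in seconds). Protocols
MPRAGE (TR ≈ 2300 ms, TE ≈ 3 ms, TI 900 ms — the only TI-bearing,
T1-volumetric protocol), T2 SPACE and FLAIR (TI 1650 ms, outside the
template range) are allocated by largest remainder, so protocol counts are
exact, then placed by seeded shuffle. Each instance carries deliberately
filtered-out content — free-text LO/PN fields, UID elements, a private
block, a sequence, a placeholder pixel payload, and (at the configured
rate) an empty-valued coded attribute. The manifest records
`n_kept_expected` per series *at construction time*, from what each element
is, giving downstream conservation tests an oracle independent of the
harvester. Headers are ~20 kept elements per series, a deliberately reduced
version of the ~61 seen in real MR series; pixel data is a placeholder, and
the fixture does not emulate manufacturer inconsistency in body-part naming
beyond random missingness. UIDs sit under the documentation OID
1.3.6.1.4.1.32473 and patients are `SYN-%04d`, so nothing can be mistaken
for real data.

**EHR fixture.** Persons, conditions and questionnaire-style measurements
with a cognitively-normal : MCI : AD mix defaulting to 133 : 151 : 87,
allocated by largest remainder and shuffled by seed. It provides the
patient→person mapping the loader needs; it does not attempt realistic
longitudinal structure.

Passing tests on these fixtures demonstrate the pipeline's counting,
mapping, filtering and query semantics exactly; they do not demonstrate
robustness to the full heterogeneity of clinical DICOM (charset diversity,
malformed headers, vendor-private conventions beyond one synthetic block).

## Numerical and degenerate-input choices

* Empty-value test: zero length after stripping whitespace and trailing
  nulls, applied before the VR test so drop reasons are attributed
  consistently.
* Missing Instance Number sorts last (2³¹) rather than failing indexing.
* A harvest of zero series is a warning, not an error; a missing person
  mapping is configurable fail-or-skip (default fail).
* Dedup ties (same code in multiple CIDs with differing meanings) keep the
  first meaning seen; meanings do not affect any count.
* Relationship rows are deduplicated on (id1, id2, type); the fixture plans
  are constructed so no planned row collides.
* `value_as_number` uses Python float parsing of the DICOM text; DS values
  in scientific notation parse, malformed numerics fall back to
  source-value-only.

## Known limitations

* Sequences are not descended, so anatomic codes nested in
  Anatomic Region Sequence are invisible; only Body Part Examined feeds the
  anatomic-site concept.
* Free-text standardization stops at the Manufacturer exception; Series
  Description is not mapped.
* Concept domain is a single configurable label (default "Measurement");
  per-concept domain assignment is unaddressed.
* The interchange schema is this package's own contract; fidelity of any
  future DocBook adapter to it is untested here.
* Measurement units are not emitted.
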