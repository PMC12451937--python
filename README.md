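# dicomop

Medical images live in PACS archives as DICOM files, while observational
research runs on structured EHR data harmonized into the OMOP Common Data
Model (CDM). The acquisition parameters that distinguish a T1-weighted
volumetric brain MRI from a FLAIR series — repetition time (TR), echo time
(TE), inversion time (TI), field strength, patient position — exist only in
DICOM headers, invisible to OMOP-based cohort tooling. `dicomop` bridges that
silo: it turns the DICOM Standard's own terminology into a custom OMOP
vocabulary and loads per-series header metadata into the OMOP medical-imaging
extension tables, so imaging phenotypes become ordinary OMOP queries.

It is aimed at imaging informaticists and OHDSI-style data engineers who need
imaging acquisition metadata queryable next to clinical tables.

## What it does

1. **Standard model** (`dicomop.standard_model`) — loads a normalized
   interchange representation of DICOM Standard content: the Part-6 attribute
   dictionary (tag, name, VR), Part-16 context groups (coded triplets
   *code value / coding scheme / code meaning* organized by CID) and the
   Body-Part-Examined→SNOMED cross-map, and Part-3 Enumerated Values /
   Defined Terms with their per-attribute value constraints.
2. **Vocabulary builder** (`dicomop.vocab_builder`) — excludes nameless
   dictionary entries, deduplicates DICOM-managed (`DCM`) codes across
   context groups (unioning CID memberships), drops Part-3 terms that
   duplicate a DCM code, and assigns every surviving attribute and value a
   non-standard concept id, consecutive from the OMOP-reserved custom range
   starting at 2 128 000 000. Relationships follow OMOP conventions:
   `Maps to value` links each attribute concept to its permitted value
   concepts; `Maps to` links DICOM body-part values to standard SNOMED
   concepts through an external-concept resolver. Emits `CONCEPT.csv` and
   `CONCEPT_RELATIONSHIP.csv`.
3. **Harvester** (`dicomop.dicom_harvester`) — indexes a patient/study/series
   DICOM tree, picks one representative instance per series (lowest Instance
   Number), extracts top-level header elements (no private tags, no pixel
   data, sequences not descended), and filters them by the VR whitelist
   `AT CS DA DT DS FL FD IS SL SS SV TM UL US UV` plus the single free-text
   exception Manufacturer (0008,0070), dropping empty values first.
4. **CDM loader** (`dicomop.cdm_loader`) — writes one Procedure_occurrence
   row per study, one Image_occurrence row per series, and one
   Image_feature + Measurement pair per kept element, resolving attribute
   tags and coded values to the custom concepts. Output is CSV plus a sqlite
   mirror.
5. **Cohort query** (`dicomop.cohort_query`) — evaluates conjunctive,
   *series-scoped* phenotype definitions (`present` / `eq` / `in_range`
   criteria plus an optional modality) identically in memory and as
   generated SQL, and exports matching person ids and Series Instance UIDs.
6. **Fixtures** (`dicomop.fixtures`) — deterministic synthetic inputs:
   standard-content bundles (including a reference profile that reproduces
   the published category counts exactly), MPRAGE/T2/FLAIR-style MR file
   trees with ground-truth manifests, and simulated EHR tables.

## Worked example

```bash
dicomop fixtures standard --profile table2 --seed 1 --out std
dicomop build-vocab --standard std --out vocab
```

prints

```
wrote 5190 attributes, 5243 coded-value occurrences to std
concepts: 5183 attributes + 3628 values; relationships: 7840 'Maps to value'
(7101 CID / 739 term) + 307 'Maps to'; grand total 16958
```

i.e. of 5190 dictionary attributes, 7 nameless ones are excluded and 5183
become Attribute concepts; 5223 DCM context-group occurrences collapse to
3281 distinct codes, joined by 318 body-part, 5 modality (74 of 79 duplicated
CID codes and were dropped), 16 patient-position and 8 compression-method
term values for 3628 Value concepts; constraints yield 7840 attribute→value
mappings and 307 body-part values map to SNOMED.

Then harvest a synthetic MR tree and query a T1-volumetric phenotype:

```bash
dicomop fixtures dicom --seed 1 --out tree
dicomop fixtures ehr --n 10 --seed 1 --out ehr
dicomop harvest --dicom-root tree --out harvest.csv
dicomop load --harvest harvest.csv --vocab vocab \
             --person-map ehr/patient_map.csv --out cdm
cat > t1vol.yaml <<'EOF'
modality: MR
criteria:
  - {attribute: "00180082", op: present}                       # TI exists
  - {attribute: "00180080", op: in_range, low: 2100, high: 2500}  # TR ms
  - {attribute: "00180081", op: in_range, low: 2, high: 4}        # TE ms
EOF
dicomop cohort --defn t1vol.yaml --cdm cdm --vocab vocab --out cohort
```

prints

```
harvested 40 series, 786 elements -> harvest.csv
loaded: {'procedure_occurrence': 5, 'image_occurrence': 40,
         'image_feature': 786, 'measurement': 786}
5 persons, 20 series -> cohort
```

— 40 series across 5 patients yield 786 filtered metadata elements (one
Image_feature + Measurement pair each), and the MPRAGE-style definition
matches exactly the 20 inversion-recovery series the fixture manifest says
it generated. `cohort/series_uids.txt` lists their Series Instance UIDs,
`cohort/cohort.sql` the equivalent parameterized SQL.

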