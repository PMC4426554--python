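# Methods

## Problem and model

Drug–drug interaction (DDI) knowledge bases assert interactions at the
level of drug *names*, and different bases disagree both in content and
in how they name drugs.  The toolkit reduces every source to one common
representation — an unordered pair of base-ingredient concepts in a
shared terminology — and then treats all comparisons as exact set
algebra.  Nothing downstream of normalization is statistical: overlap,
reference coverage, class-pair Jaccard and screening matches are
deterministic functions of the normalized sets, which is why the test
suite demands exact recovery of planted ground truth rather than
agreement within a tolerance.

## Terminology and name resolution

The terminology models three concept levels: ingredients (base active
moieties), precise ingredients (salt/ester forms linked to their base),
and clinical drugs (dispensable products linked to one or more
ingredients, with a route class used only for the topical filter).
Real-world systems resolve names through a terminology service with an
"exact or normalized" string match; here the normalized match is an
explicit local rule — case-fold, strip the punctuation `,.;:'"()/-`,
collapse whitespace — chosen to be deterministic and idempotent rather
than to replicate any service's internal behavior.  Consequences of this
design:

* Two concepts whose names collide after normalization abort the load;
  there is no disambiguation rule worth inventing, and a colliding
  terminology is better rejected than silently arbitrated.
* Obsolete concepts load but never resolve, so records referencing them
  are discarded downstream as unmapped — mirroring how interaction
  records tied to retired terminology entries behave in practice.
* Misspellings resolve only if the terminology contains the same
  misspelling; there is deliberately no fuzzy matching.

## Normalization accounting

Every discarded record is classified exactly once:

| counter | condition |
|---|---|
| `unmapped_ddis` | either name fails to resolve (or hits only an obsolete concept) |
| `multi_ingredient_dropped` | a name resolves to a clinical drug; interaction assertions live at ingredient level, so product-level records are dropped rather than expanded (expansion is the screening module's job) |
| `self_pairs_dropped` | both names collapse to the same ingredient (e.g. two salts of one moiety) — meaningless at ingredient level |
| `collapsed_duplicates` | the canonical pair already exists (salt-form redundancy) |

so `output = input − unmapped − multi − self − duplicates` holds on
every run; the report constructor enforces the equation.  On duplicate
merge the higher severity wins (critical > significant; conservative for
alerting) and the lexicographically smallest description is kept, making
the output invariant under permutation of the input list.

## Percentages and Jaccard

Printed coverage figures use half-up rounding to an integer percent,
implemented in exact integer arithmetic (`floor((200n + d) / 2d)`), which
reproduces the conventional roundings such as 207/360 → 58%.  Class-pair
Jaccard scores are carried at full precision and rounded to two decimals
only in rendered tables.

## Class abstraction choices

Only pairs whose *both* members carry at least one 4th-level ATC class
are analysed; the excluded count is reported.  An ingredient with
several classes fans the interaction out to every class-pair
combination — no primary-class heuristic — so per-class-pair counts sum
to at least the plain intersection size, with equality exactly when
every ingredient is single-class (property-tested).  Same-class pairs
are legal and keyed `(c, c)`.

## Screening semantics

One prescription list is one co-prescription event: within-list
duplicate ingredient pairs (possible via combination products sharing an
ingredient) count once per list.  Topical products are removed before
pairing because ingredient-level interaction knowledge refers to
systemic exposure.  The prescriptions CSV may carry a `count` column,
interpreted as a repeat weight of the whole patient list (it must be
uniform within a patient); pair occurrences are weighted accordingly.
"Matched by both sources" is computed against the intersection of the
source pair sets, not by intersecting per-source match events.

## Synthetic data

The generator emulates the statistical structure of real interaction
sources, at desk scale, with every planted quantity recorded in a ground
-truth ledger:

* a terminology of `n_ingredients` (default 300) pseudo-named
  ingredients, ~30% with a salt form, one single-ingredient product per
  ingredient plus combination products so that ~20% of products are
  two-ingredient, ~15% of products topical, ~12% of ingredients outside
  ATC (real sources leave 11–14% of drugs unclassed);
* two sources (defaults 500 and 600 interactions) with a planted
  overlap (default 150, i.e. 25–30% mutual coverage as observed between
  public DDI sources), source A severity-annotated with about one third
  critical;
* salt-form name noise: with probability `salt_noise_rate` a drug name
  is emitted as its salt form, and redundant salt-form re-assertions of
  the same interaction are planted at half that rate — these are what
  normalization must collapse, so `salt_noise_rate = 0` implies zero
  collapsed duplicates;
* extra records with out-of-terminology names (default 5% of source
  size) that must surface as unmapped;
* prescription lists with lengths from a truncated geometric
  distribution (mean 4 drugs, minimum 1) and optional planted
  interacting pairs at target frequencies; ingredients of planted pairs
  are forced to have systemic products so the plant survives the topical
  filter.

The ledger's screening totals are computed by an independent nested-loop
expansion inside the generator, so the screening module is checked
against bookkeeping it cannot share code with.  What the generator does
*not* emulate: real pharmacology (which ingredients plausibly interact),
the heavy-tailed co-prescription frequency distribution of real claims
data, brand names, dose forms, and spelling variation between sources.
Passing recovery tests therefore demonstrates correctness of the
pipeline's algebra and accounting, not robustness to real-world name
noise beyond salt forms.

## Problem sizes

The default test suite runs the full pipeline on bundles of 80–300
ingredients and 100–2000 interactions per source, including a 20-seed
exact-recovery sweep; these sizes exercise every code path while keeping
the whole suite in the seconds-to-minutes range.  All randomness is
seeded; the generator is byte-deterministic in its seed.

## Known limitations

* The normalized string match is a stand-in for terminology-service
  matching, not a claim of equivalence.
* Reference-group member names must resolve in the terminology used;
  members that do not resolve are silently absent from that group's
  canonical pairs (the packaged reference list is only expanded at the
  name level, where no terminology is needed).
* No statistical testing of overlap is performed; the comparisons are
  descriptive counts, which is what the underlying study design calls
  for.
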