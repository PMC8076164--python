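# Methods

This note documents the conventions, modeling choices and known limitations
behind `hebkeys`.  The package reimplements, as tested code, the
computational content of a multi-decade inventory of Greenland *Hebeloma*
collections: the
morphometric measurement protocol, the four identification keys, the
region/zone/distribution-group scheme, the collection catalogue tabulations,
and the ITS-variant construction.  No empirical claim is made here that the
test suite or `scripts/acceptance.py` does not itself compute.

## Morphometric conventions

* **Percentiles.**  The 5%/95% figures are linear interpolation between
  order statistics (the "type 7" estimator, numpy's default).  The source
  descriptions do not state the estimator; the choice is configurable
  (`percentile_method` of `summarize_spores`) and only affects small samples.
* **Standard deviation.**  Sample SD (n−1), since a collection's spores are a
  sample from the basidiome.
* **Ratios.**  Q and the cystidium ratios A/M, A/B, B/M are means of
  per-item ratios.  The ratio of means is reported as a diagnostic field
  (`ratio_of_means_am`) because the two can differ materially — e.g.
  aggregate cystidium means of 7.4 (apex) and 5.0 (middle) give a
  ratio-of-means of 1.48 while the mean-of-ratios for the same species is
  reported as 1.5–2.3 — but the keys never consume it.
* **Protocol floors.**  ≥ 50 spores, ≥ 20 full cystidia and ~100 apex widths
  per collection are "wherever possible" targets: smaller samples raise
  warning flags (`n_below_protocol`, …), never errors.
* **Ordinal codes.**  O/P/D class strings are parsed order-insensitively;
  parenthesized classes carry a `parenthetical` qualifier.  A key lead that
  demands "many spores X" is satisfied only by a non-parenthetical X; "X
  present" counts rare states too.

## Key transcription and semantics

The keys are data (`data/keys.json`), not code: couplets with two leads,
each a predicate tree (`and`/`or`/`not` over numeric comparisons, categorical
equality and O/P/D class tests) plus an outcome.  Conventions:

* Where the printed alternative is verbal ("Spores smaller", "The above
  conditions not satisfied"), the lead is the complement of its sibling, so
  every numeric threshold is half-open exactly once.  Where both leads are
  printed conditions, both are transcribed (the sect. *Hebeloma* key's
  width/shape couplet 12 is genuinely non-dichotomous, and is kept so).
* Qualitative couplets ("cap distinctly bicolored", "cap often overhanging
  lamellae", "dark reddish tones", "pileus with a matting of short soft
  hairs") are driven by explicit boolean profile fields
  (`cap_bicolored`, `cap_overhanging`, `cap_dark_reddish`,
  `pileus_pubescent`); no color arithmetic is attempted.
* Evaluation is Kleene three-valued; traversal follows the first true lead,
  follows every unresolved lead when the profile leaves predicates unknown
  (returning the union of reachable taxa), and — when a profile satisfies
  neither printed lead — explores both leads and flags the couplet
  `no_lead_matched` in the path.

### Known inconsistencies in the printed keys (reported, not repaired)

The audit (`validate_keys_against_taxa`) routes every species' centroid
profile (interval midpoints + recorded categorical states) through the keys:

1. ***H. arcticum***: described with almost smooth (O1) spores, but its
   couplet in the *Denudata* key demands "Spores O2 to O3 … many D3", and
   the escape lead requires "at most D2" (the species is D2D3).  Neither
   lead holds; the traversal flags the couplet and returns
   {*arcticum*, *louiseae*}.
2. ***H. ingratum*** (O2O3, D1D2, P2) satisfies the sections-key couplet
   intended for *H. hiemale* ("many O1 or O2 and many D0 or D1 …"), so its
   centroid terminates at *H. hiemale*.  Entering the *Denudata* key at the
   hourglass couplet directly identifies it correctly.
3. ***H. aurantioumbrinum***: its mean spore-length range 10.0–12.0 µm has
   midpoint exactly 11.0, the "< 11 µm" threshold of the *Denudata* key;
   the centroid takes the ≥ 11 branch and lands on *H. louiseae*.

These appear in the validation report as conflicts; in addition the report
lists **boundary collisions** — numeric thresholds lying within a species'
described range at couplets on its own traversal (e.g. *H. spetsbergense*'s
width range 7.5–8.5 touching the "> 7.5 µm" lead).  Real collections of such
species can land on either side of the couplet, so only collision-free
species are held to exact closed-loop identification in the tests.

* *H. islandicum* is recorded with `veil_present = false` and
  `cheilocystidia_form = hourglass` so that the printed sections key (which
  routes it through the veil-absent, hourglass branch) is reproducible; its
  description hedges on both characters ("sometimes with remnants of
  universal veil", cystidia "a mixture"), and its A/M and B/M ratios (> 1 at
  both ends) support the hourglass reading.

## Trait database

One record per species compiles the "on ave." ranges (the keys compare
collection means, so where a description gives both an absolute and an
"on ave." interval the latter is stored), the lamellae count range {L}, the
O/P/D code strings, cystidium dimension ranges, key-relevant qualitative
characters, hosts, and the distribution group / specialist–opportunist
classification with collection counts.  Qualitative traits a description
does not state are `null` (unknown), never false.  Two source
inconsistencies are carried as-is: *H. marginatulum* is stored with the
table count of 42 collections (its habitat paragraph says forty-five; the
voucher table supports 42), and the catalogue's 367 full-ITS + 10
partial-ITS records sum to 377 against a stated total of 378 — the fixture
keeps all 378 voucher-table rows and the 10 partial flags.

## Catalogue fixture

`data/catalogue.csv` transcribes the voucher table merged with the
per-species collection paragraphs: coordinates are decimal degrees with west
longitudes negative; dates are ISO; the paragraphs' S-/W-/N-/E-Greenland
headings are kept as an explicit `region` column that takes precedence over
the coordinate rule (useful where a locality sits near the configurable
44°W east/west divide).  A handful of typographic defects in the source
(a missing parenthesis, a coordinate printed without the degree sign, two
collector-number mix-ups between species) were resolved by eye against the
surrounding text during transcription.

## Biogeography conventions

* Boundaries at 62.20°N and 74°N belong to the northern side; both are
  configurable, as is the 70°N Low/High Arctic split — a single-latitude
  approximation of a boundary that actually runs from central Disko Island
  to the Blosseville Coast.
* The east/west divide meridian defaults to 44°W, which separates all
  west-coast sites (48–56°W) from all east-coast sites (17–37°W) in the
  62.2–74°N band; it is an approximation of the ice-sheet divide, not a
  printed value.
* The Subarctic zone is botanically defined (co-occurrence of *Sagina
  nodosa* and *Eleocharis quinqueflora*) and therefore never inferred from
  coordinates: it enters the analysis only through an explicit site flag or
  the < 61.25°N cutoff used for the subarctic species count.
* Group mapping from a species' region set: no South → 5; South and North →
  4; {S} → 1; {S,W} → 2; otherwise (South and East, no North) → 3.  The
  mapping is total and reproduces the published grouping for all 28 species.

## ITS variants

Two aligned consensus sequences share a variant iff identical column by
column: gaps are significant (indels treated as insertions — alignment
columns count like substitution columns) and IUPAC ambiguity codes compare
as literal symbols, because the ambiguities are part of the per-collection
consensus.  A relaxed mode treating compatible codes as equal exists for
exploration but is off by default, is order-dependent (compatibility is not
transitive), and is not used anywhere in the pipeline.  Distances are plain
Hamming counts over columns.  The quasi-median network construction and
pruning that consumes these distances is external software and out of scope;
this module stops at the variant/distance/sharing layer.

## Synthetic data

* **Specimens.**  The "on ave." interval is read as a ±2 SD envelope of the
  collection mean: a latent mean is drawn from a truncated normal centred at
  the midpoint with SD = width/4, truncated to the interval; measurements
  scatter around it with 5% relative noise (configurable).  This calibration
  is a modeling choice the source cannot pin down; it guarantees collection
  means stay inside the described range, so identification errors on
  synthetic data trace back to genuine key boundaries, not generator drift.
* Parenthetical O/P/D classes are sampled in at probability 0.25 and remain
  flagged parenthetical; ordinary classes are always recorded.
* **Catalogues.**  Collections are placed with uniform jitter around the
  five main survey localities (Narsarsuaq, Paamiut, Kangerlussuaq,
  Zackenberg, Jameson Land), covering exactly the region set of each
  species' distribution group, so `tabulate_groups` recovers every group.
  Hosts are sampled uniformly from each species' recorded host list and are
  metadata only.
* **What the generator does not emulate:** collection-effort bias, real
  within-species covariance between traits, intra-collection host mixtures,
  or realistic sequence evolution (toy alignments are engineered variant
  classes, not simulated ITS).  Passing closed-loop tests therefore shows
  the keys and statistics are internally consistent with the described
  ranges — not that field identification of real material reaches the same
  accuracy.

## Problem sizes and determinism

The shipped tests run the full pipeline at survey scale (378 catalogue rows,
28 species) and the stochastic suites at 10–300 seeded replicates per
property; `scripts/acceptance.py` uses 20 seeded replicates for the closed
identification loop and 200 for parameter recovery, deriving all randomness
from its `--seed` argument.  All generators take explicit integer seeds and
are bit-for-bit reproducible.
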