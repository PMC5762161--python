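# Packaged example datasets

Both datasets come from a published colorectal-cancer study comparing a short
neoadjuvant course of radiotherapy ("Short RT", subjects 7-12) against no
radiotherapy ("None", subjects 1-6), with the resection specimen as the tissue
source. Treatment is applied at the subject level, so the subject is the
experimental unit in both designs. Values are transcribed verbatim from the
printed tables; dashes in the printed tables mean "no observation taken" and
are absent records here, not zeros.

## lymph_size.csv (continuous outcome, fully balanced)

Maximum lymph-node diameter in mm, measured on slice images. Each of the 12
subjects contributed 2 tissue sub-samples, and 3 slices were measured per
sub-sample: 72 records in total. Checked marginals: group means 2.403 mm
(None) and 2.120 mm (Short RT).

Columns: `group, subject, sample, replicate, value`; `sample` and `replicate`
are nested labels (sample "1" of subject 1 is unrelated to sample "1" of
subject 2).

## lymph_count.csv (binomial outcome, unbalanced)

For each tissue sample, five lymph nodes were randomly selected in regions of
interest and each compared against a 2 mm reference: the record is the number
of the 5 nodes with diameter >= 2 mm. Up to five samples per subject were
available (some subjects had insufficient tissue): 50 records, 25 per group.
Checked marginals: 79 events out of 125 trials (None), 43 out of 125
(Short RT).

Columns: `group, subject, sample, events, trials` with `trials = 5`
throughout.
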