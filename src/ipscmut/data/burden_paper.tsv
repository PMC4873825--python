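# Published per-line de novo mutation burdens for the two repair-deficiency
# classes (XPA: nucleotide-excision-repair deficient, two lines from two
# patients; ATM: double-strand-break-repair deficient, four lines from one
# patient).
#
# The four ATM per-line indel counts were never printed as integers; only the
# pooled indel fraction (30.1%) is text-derived, giving a reconstructed pooled
# total of round(167 * 0.301 / 0.699) = 72 indels. That total is spread evenly
# here (18 per line) purely so the file type-checks; every statistic this
# package computes from this table uses only the pooled ATM indel total, which
# is unaffected by the split.
sample	label	n_snv	n_indel	passage_number
XPAiPS-O1	XPA	229	24
XPAiPS-E3	XPA	174	20
AT-iPS-1	ATM	43	18
AT-iPS-2	ATM	48	18
AT-iPS-3	ATM	35	18
AT-iPS-4	ATM	41	18
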