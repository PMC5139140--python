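# Seed keyword list hinting a citation should be INCLUDED.
# Phrases indicative of randomized-controlled-trial reports, in the spirit of
# the published EMBASE RCT search filter; edit freely (one phrase per line,
# '#' starts a comment).
randomized
randomised
randomization
randomisation
randomly
random allocation
randomized controlled trial
randomised controlled trial
controlled clinical trial
clinical trial
placebo
double blind
single blind
triple blind
blinded
crossover
cross over
parallel group
allocation concealment
intention to treat
trial
trials
rct
multicenter study
prospective study
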