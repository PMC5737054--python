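# Lead-in phrases stripped from raw queries before tokenization.
# One literal phrase per line; matching is lowercase and word-bounded.
# This list is configuration: edit or replace it per collection.
search for
searching for
search
find all
find
look for
looking for
show me
give me
retrieve
information about
information on
i am interested in
i need
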