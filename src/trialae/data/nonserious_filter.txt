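# Placeholder list of commonly shared nonserious adverse events to exclude
# from top-event selection. Supply your own list for real analyses; this
# default only illustrates the mechanism. One canonical term per line.
headache
fatigue
nausea
nasopharyngitis
diarrhea
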