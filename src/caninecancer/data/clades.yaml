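# Editable breed -> clade mapping, keyed to the 23-clade genetic
# relatedness scheme for dog breeds. Pre-populated with commonly cited
# members only; extend to the full scheme as needed for your tables.
# Clade labels (partial): terrier, pointer/setter, spaniel, retriever,
# scent hound, toy, herding (UK rural), European mastiff, alpine, drover,
# nordic, asian spitz.
Scottish terrier: terrier
Cairn terrier: terrier
Staffordshire bull terrier: terrier
West Highland white terrier: terrier
Yorkshire terrier: terrier
Soft-coated wheaten terrier: terrier
English setter: pointer/setter
Irish setter: pointer/setter
Gordon setter: pointer/setter
English pointer: pointer/setter
Brittany: pointer/setter
Flat-coated retriever: retriever
Golden retriever: retriever
Labrador retriever: retriever
Great Dane: European mastiff
Bullmastiff: European mastiff
Bulldog: European mastiff
Saint Bernard: alpine
Bernese mountain dog: alpine
Rottweiler: drover
Irish wolfhound: UK rural
Greyhound: UK rural
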