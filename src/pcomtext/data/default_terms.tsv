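# Default curated term lists (stemmed n-grams, space-joined).
# category	ngram
# Volume confounders: structures that enlarge an ovary for reasons
# other than stromal/follicular excess.
confounder	domin follicl
confounder	corpus luteum
confounder	dermoid
confounder	dermoid cyst
confounder	hemorrhag cyst
confounder	simpl cyst
confounder	complex cyst
# Classical polycystic-morphology descriptors.
pcom_phrase	numer peripher follicl
pcom_phrase	string pearl
pcom_phrase	polycyst ovari
pcom_phrase	polycyst ovari syndrom
pcom_phrase	ovari syndrom
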