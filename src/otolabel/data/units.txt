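mm
cm
ml
cc
khz
hz
db
year
years
month
months
week
weeks
day
days
degree
degrees
second
seconds
minute
minutes
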