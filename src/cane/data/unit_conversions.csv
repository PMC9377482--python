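from_unit,to_unit,formula_id
degF,Cel,fahrenheit_to_celsius
[degF],Cel,fahrenheit_to_celsius
Cel,degF,celsius_to_fahrenheit
%,1,percent_to_fraction
1,%,fraction_to_percent
kPa,mm[Hg],kilopascal_to_mmhg
mm[Hg],kPa,mmhg_to_kilopascal
10*9/L,10*3/uL,identity
10*3/uL,10*9/L,identity
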