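# Mechanism x intent ICD code ranges, version 1.
# mechanism: HSS = hanging/strangulation/suffocation, AUT = autointoxication, FA = firearm,
#            ANY = not mechanism-specific (sequelae of self-inflicted injury).
# provenance: printed = taken from the published mapping; inferred = natural completion
#             (intentional self-harm codes for HSS and AUT are not printed in the source table).
mechanism,intent,icd_revision,code_start,code_end,provenance
FA,suicide,9,E955,E955,printed
FA,suicide,10,X72,X74,printed
HSS,suicide,9,E953,E953,inferred
HSS,suicide,10,X70,X70,inferred
AUT,suicide,9,E950,E952,inferred
AUT,suicide,10,X60,X69,inferred
HSS,accident,9,E913,E913,printed
HSS,accident,10,W75,W76,printed
AUT,accident,9,E850,E869,printed
AUT,accident,10,X40,X49,printed
FA,accident,9,E922,E922,printed
FA,accident,10,W32,W34,printed
HSS,assault,9,E963,E963,printed
HSS,assault,10,X91,X91,printed
AUT,assault,9,E962,E962,printed
AUT,assault,10,X85,X90,printed
FA,assault,9,E965,E965,printed
FA,assault,10,X93,X95,printed
HSS,undetermined,9,E983,E983,printed
HSS,undetermined,10,Y20,Y20,printed
AUT,undetermined,9,E980,E982,printed
AUT,undetermined,10,Y10,Y19,printed
FA,undetermined,9,E985,E985,printed
FA,undetermined,10,Y22,Y24,printed
ANY,sequelae,9,E959,E959,printed
ANY,sequelae,10,Y87,Y87,printed
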