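# Manually transcribed published morph table for the East African chimpanzee
# gesture repertoire (115 morphs over 42 gesture actions).  The printed
# source runs cells together; rows where the count abuts the accuracy with
# no intervening modifier cell are flagged in the note column and their
# counts must not be relied on.  Placement of single body-part cells in the
# signaller vs contact column is not recoverable from the print and was
# assigned per action by plausibility.  NV = modifier not valid given
# another modifier's level; blank = unconstrained; "|" = either level.
morph_name,count,body_part_signaller,body_part_contact,repetition,laterality,unexplained,prediction_accuracy,note
Beckon.1,18,Arm,,,,,0,
Beckon.2,12,Hand,,,,,0.25,
BigLoudScratch.1,344,,Body,,Unimanual,,0.69,
BigLoudScratch.2,219,,Arm,,Unimanual,,0.05,
BigLoudScratch.3,183,,Head,,Unimanual,,0.72,
BigLoudScratch.4,74,,Leg,,,,0.06,
BigLoudScratch.5,24,,Back|Face,,Unimanual,,0.62,
BigLoudScratch.6,6,,,,Both,,0,
Bite.1,19,,Face|Hand|Head|Leg|None,,,,0.16,
Bite.2,42,,Back,,,,0.16,
Bite.3,25,,Arm,,,,0,
Bite.4,25,,Body,,,,0.43,
Bounce.1,14,,,,,,0.42,count/accuracy boundary ambiguous in source
Bow.1,12,,,,,,0.17,count/accuracy boundary ambiguous in source
Dangle.1,241,,,,,,0.83,count/accuracy boundary ambiguous in source
DangleShake.1,40,,,,,,0.32,count/accuracy boundary ambiguous in source
Drum.1,23,,,,,,0.34,count/accuracy boundary ambiguous in source
Embrace.1,34,,Body,,Both,,0.77,
Embrace.2,23,,Body,,Unimanual,,0.65,
Embrace.3,19,,Back,,Unimanual,,0.28,
Embrace.4,5,,Back,,Both,,1,
Fling.1,70,Arm,,,,,0.81,
Fling.2,28,Hand,,,,,0.63,
Grab.1,47,,Leg,,Unimanual,,0,
Grab.2,43,,Face|Hand|Head,,Unimanual,,0.13,
Grab.3,41,,Back,,Unimanual,,0,
Grab.4,28,,Arm,,Unimanual,,0.08,
Grab.5,26,,Body,,Unimanual,,0.02,
Grab.6,17,,,,Both,,0.25,
GrabHold.1,53,,Arm|Back|Body|Face|Hand|Head,,Unimanual,,0,
GrabHold.2,31,,Leg,,Unimanual,,0.02,
GrabHold.3,25,,,,Both,,0.05,
HeadStand.1,38,,,,,,0.19,count/accuracy boundary ambiguous in source
HitObject.1,294,Hand,,No,Unimanual,,0.25,
HitObject.2,60,Hand,,No,Both,,0.13,
HitObject.3,39,Foot,,No,,,0.03,
HitObject.4,34,,,,,1,0,All other cases
HitObject.5,32,Hand,,Yes,Unimanual,,0.08,
HitObject.6,16,Foot,,Yes,,,0,
HitOther.1,113,Hand,Arm|Body|Face|Hand|Genitals|Head|Leg,No,Unimanual,,0.13,
HitOther.2,55,,,Yes,Unimanual,,0.02,
HitOther.3,55,Hand,Back,No,Alternating|Unimanual,,0.17,
HitOther.4,34,,,Yes,Alternating|Both,,0.96,
HitOther.5,30,Fingers|Foot,,No,Unimanual,,0.20,
HitOther.6,29,,,No,Both,,0,
Jump.1,38,,,,,,0,count/accuracy boundary ambiguous in source
KickPunch.1,10,,,,,,0.2,count/accuracy boundary ambiguous in source
LeafClip.1,31,Hand,,,Unimanual,,0.77,
LeafClip.2,19,Face,,,NV,,0.95,
LocomoteGallop.1,49,,,,,,0.89,count/accuracy boundary ambiguous in source
Lunge.1,13,,,,,,0.2,count/accuracy boundary ambiguous in source
ObjectMouth.1,31,,,,,,0.14,count/accuracy boundary ambiguous in source; stray character in print
ObjectMove.1,211,,,,Unimanual,,0.10,
ObjectMove.2,37,,,,Both,,0.07,
ObjectShake.1,402,Hand,,Yes,Unimanual,,0.51,
ObjectShake.2,135,Hand,,Yes,Alternating|Both,,0.13,
ObjectShake.3,18,Foot,,Yes,,,0.25,
ObjectShake.4,17,,,No,,,0.8,
Poke.1,12,,,,,,0,count/accuracy boundary ambiguous in source
Present.1,197,Back,,,,,0.32,
Present.2,144,Arm,,,,,0.25,
Present.3,120,Body,,,NV,,0.31,
Present.4,94,Leg,,,,,0.43,
Present.5,50,Bottom,,,,,0.26,
Present.6,21,Head,,,,,0.75,
Present.7,13,Body|Foot,,,Unimanual,,0.1,
PresentGenitals.1,283,,Genitals,,,,0.75,
PresentGenitals.2,60,,Bottom,,,,0.43,
Pull.1,59,,Back|Body|Face|Hand,,Unimanual,,0.06,
Pull.2,54,,Leg,,Unimanual,,0.02,
Pull.3,44,,Arm,,Unimanual,,0.24,
Pull.4,25,,,,Both,,0.24,
Push.1,99,Hand,Back,,Unimanual,,0.19,
Push.2,92,Hand,Body|Face|Hand|Head,,Unimanual,,0.49,
Push.3,65,Hand,Leg,,Unimanual,,0.86,
Push.4,54,Fingers,,,,,0.58,
Push.5,47,Hand,Arm,,Unimanual,,0.15,
Push.6,18,,,,Both,,0.53,
Push.7,16,Foot,,,,,0.1,
Raise.1,201,Arm,,,Unimanual,,0.32,
Raise.2,24,Hand,,,,,0,
Raise.3,8,,,,Both,,0.38,
Reach.1,370,Arm,,,,,0.37,
Reach.2,191,Hand,,,,,0.70,
Reach.3,16,Leg,,,,,0,
Rocking.1,36,,,,,,0.70,count/accuracy boundary ambiguous in source
RollOver.1,34,,,,,,0,count/accuracy boundary ambiguous in source
Rub.1,21,,,No,,,0.43,
Rub.2,19,,Genitals,Yes,,,0.83,
Rub.3,7,,Bottom,Yes,,,0.67,
Shake.1,36,,,,Unimanual,,0,
Shake.2,23,Head,,,NV,,0.55,
Shake.3,16,,,,Alternating|Both,,0.87,
SpinRoulade.1,23,,,,,,0.47,count/accuracy boundary ambiguous in source
SpinSomersault.1,42,,,,,,0.39,count/accuracy boundary ambiguous in source
StompObject.1,213,Foot,,No,Unimanual,,0.06,
StompObject.2,93,,,Yes,Alternating,,0.71,
StompObject.3,49,,,Yes,Unimanual,,0.19,
StompObject.4,38,Foot,,,Both,,0.87,
StompObject.5,13,,,No,Alternating,,0.17,
StompObject.6,8,Hand,,,,,0.25,
StompOther.1,12,,Back,No,,,0,
StompOther.2,8,,,Yes,,,1,
StompOther.3,6,,Other,No,,,0.33,
Stroke.1,16,Hand,,No,,,0,
Stroke.2,12,,,Yes,,,0,
Stroke.3,8,Fingers,,No,,,0,
Swing.1,259,Arm,,,,,0.13,
Swing.2,18,Leg,,,,,0.18,
ThrowObject.1,20,,,,,,0.33,count/accuracy boundary ambiguous in source
Touch.1,144,Hand,Arm|Face|Hand|Genitals|Head,,,,0.13,
Touch.2,119,Fingers|Other,,,,,0.01,
Touch.3,88,Hand,Back,,,,0.07,
Touch.4,54,Hand,Leg,,,,0.14,
Touch.5,42,Hand,Body,,,,0.1,
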