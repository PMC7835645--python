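# Neurological Deficit Scale rubric, version 1.
#
# Six assessment blocks; each component has an enumerated set of
# (label, subscore) levels.  Block maxima: arousal 19, brainstem 21,
# motor 6, sensory 6, motor_behavioral 6, behavioral 12; best total 70,
# worst 0.  Limb strength and pain response are tested on each forelimb
# separately (two entries of max 3 each).
#
# Encoding notes (editable):
#   - respiration "normal" carries 6 points (10 + 3 + 6 = 19 arousal max);
#   - turning_alley scores abnormal performance 0, as printed in the
#     source instrument, unlike the other behavioral items (3/1/0).

version = "1"

[[component]]
name = "consciousness"
assessment = "arousal"
levels = [["normal", 10], ["lethargic", 5], ["comatose", 0]]

[[component]]
name = "eyes"
assessment = "arousal"
levels = [["open_independently", 3], ["open_to_pain", 1], ["absent", 0]]

[[component]]
name = "respiration"
assessment = "arousal"
levels = [["normal", 6], ["abnormal", 3], ["absent", 0]]

[[component]]
name = "olfaction"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "vision_reflex"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "pupillary_reflex"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "corneal_reflex"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "startle_reflex"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "whisker_stimulation"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "swallowing"
assessment = "brainstem"
levels = [["present", 3], ["absent", 0]]

[[component]]
name = "limbs_left"
assessment = "motor"
levels = [["normal", 3], ["weak", 1], ["no_movement", 0]]

[[component]]
name = "limbs_right"
assessment = "motor"
levels = [["normal", 3], ["weak", 1], ["no_movement", 0]]

[[component]]
name = "pain_response_left"
assessment = "sensory"
levels = [["brisk", 3], ["weak", 1], ["no_movement", 0]]

[[component]]
name = "pain_response_right"
assessment = "sensory"
levels = [["brisk", 3], ["weak", 1], ["no_movement", 0]]

[[component]]
name = "gait"
assessment = "motor_behavioral"
levels = [["normal", 3], ["abnormal", 1], ["absent", 0]]

[[component]]
name = "balance_beam"
assessment = "motor_behavioral"
levels = [["normal", 3], ["abnormal", 1], ["absent", 0]]

[[component]]
name = "righting_reflex"
assessment = "behavioral"
levels = [["normal", 3], ["abnormal", 1], ["absent", 0]]

[[component]]
name = "negative_geotaxis"
assessment = "behavioral"
levels = [["normal", 3], ["abnormal", 1], ["absent", 0]]

[[component]]
name = "spatial_awareness"
assessment = "behavioral"
levels = [["normal", 3], ["abnormal", 1], ["absent", 0]]

[[component]]
name = "turning_alley"
assessment = "behavioral"
levels = [["normal", 3], ["abnormal", 0], ["absent", 0]]
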