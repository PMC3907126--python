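name: RAADS-14 Screen
categories:
  - true now and when I was young
  - true only now
  - true only when I was younger than 16
  - never true
forward_scores:
  true now and when I was young: 3
  true only now: 2
  true only when I was younger than 16: 1
  never true: 0
screen_cutoff: 14
short_form_cutoff: 4
max_missing: 4
items:
  - item_id: 1
    text: It is difficult for me to understand how other people are feeling when we are talking
    reversed: false
    original_domain: social_relatedness
    subscale: mentalizing_deficits
    short_form: true
  - item_id: 2
    text: Some ordinary textures that do not bother others feel very offensive when they touch my skin
    reversed: false
    original_domain: sensory_motor
    subscale: sensory_reactivity
    short_form: true
  - item_id: 3
    text: It is very difficult for me to work and function in groups
    reversed: false
    original_domain: social_relatedness
    subscale: social_anxiety
    short_form: true
  - item_id: 4
    text: It is difficult to figure out what other people expect of me
    reversed: false
    original_domain: social_relatedness
    subscale: mentalizing_deficits
    short_form: true
  - item_id: 5
    text: I often don’t know how to act in social situations
    reversed: false
    original_domain: social_relatedness
    subscale: social_anxiety
    short_form: true
  - item_id: 6
    text: I can chat and make small talk with people
    reversed: true
    original_domain: language
    subscale: social_anxiety
    short_form: false
  - item_id: 7
    text: When I feel overwhelmed by my senses, I have to isolate myself to shut them down
    reversed: false
    original_domain: sensory_motor
    subscale: sensory_reactivity
    short_form: false
  - item_id: 8
    text: How to make friends and socialize is a mystery to me
    reversed: false
    original_domain: social_relatedness
    subscale: social_anxiety
    short_form: false
  - item_id: 9
    text: When talking to someone, I have a hard time telling when it is my turn to talk or to listen
    reversed: false
    original_domain: social_relatedness
    subscale: mentalizing_deficits
    short_form: false
  - item_id: 10
    text: Sometimes I have to cover my ears to block out painful noises (like vacuum cleaners or people talking too much or too loudly)
    reversed: false
    original_domain: sensory_motor
    subscale: sensory_reactivity
    short_form: false
  - item_id: 11
    text: It can be very hard to read someone’s face, hand, and body movements when we are talking
    reversed: false
    original_domain: social_relatedness
    subscale: mentalizing_deficits
    short_form: false
  - item_id: 12
    text: I focus on details rather than the overall idea
    reversed: false
    original_domain: circumscribed_interests
    subscale: mentalizing_deficits
    short_form: false
  - item_id: 13
    text: I take things too literally, so I often miss what people are trying to say
    reversed: false
    original_domain: language
    subscale: mentalizing_deficits
    short_form: false
  - item_id: 14
    text: I get extremely upset when the way I like to do things is suddenly changed
    reversed: false
    original_domain: circumscribed_interests
    subscale: mentalizing_deficits
    short_form: false
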