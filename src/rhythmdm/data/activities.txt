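Preparing food
Eating or drinking
Cleaning my home/room
Laundry
Budgeting or paying bills
Showering or grooming
Changing clothes
Watching TV
Using social media
Shopping online
Other internet/computer/tablet use
Reading, Writing, or journaling
Gardening
Social interactions
Working (paid)
Volunteering
Unpaid work
Meditating
Private religious activities
Listening to music
Arts and crafts
Playing a musical instrument
Doing nothing
Other activities
Eating or drinking out
Other physical leisure
Schoolwork
Looking for a job
Shopping
Entertainment (cinema, sports, etc.)
Riding in a bus, trolley, car, or van
Visiting the beach or park
Visiting family or friends
Exercising
Other non-physical leisure
Resting
Attending meetings (church, AA, etc.)
Smoking
Doing laundry at a laundromat
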