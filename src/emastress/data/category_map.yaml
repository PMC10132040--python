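# Seed app-categorization scheme: 18 core smartphone app categories with
# example apps per category. Lookup is performed on a normalized app name
# (lowercased, non-alphanumerics stripped), so "WhatsApp Messenger" and
# "whatsapp" both resolve to messenger. Extend freely; every top-level key
# must be one of the 18 core category labels.
browser:
  - Chrome
  - Opera
  - Firefox
calling:
  - Phone
  - Dialer
  - Call
camera:
  - Camera
dating:
  - Tinder
  - Grindr
email:
  - Gmail
  - Outlook
exercise:
  - RunKeeper
  - Strava
food_drink:
  - UberEATS
  - Thuisbezorgd
gallery:
  - Gallery
  - Photos
game:
  - CandyCrush
  - Candy Crush Saga
messenger:
  - WhatsApp
  - WhatsApp Messenger
  - Telegram
music_audio:
  - Spotify
productivity:
  - Microsoft Word
  - Word
  - Docs
shared_transportation:
  - 9292OV
  - 9292
social_network:
  - Facebook
  - Instagram
  - Twitter
tracker:
  - Pedometer
  - Step Counter
video:
  - YouTube
  - Netflix
weather:
  - Weather
  - Buienradar
work:
  - StudentJob
  - EmployeeApp
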